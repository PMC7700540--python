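"""Denoising, delay compensation, min-max normalization, and framing.

Pipeline order: third-order median filter -> moving average ->
normalization -> overlapped framing. Both filters use edge replication
so output length equals input length, and both are range-contractive
(output min/max never exceed input min/max per axis).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import SignalStream, WindowFrame

log = logging.getLogger(__name__)


def _medfilt3_1d(v: np.ndarray) -> np.ndarray:
    if len(v) < 2:
        return v.copy()
    p = np.pad(v, 1, mode="edge")
    stacked = np.stack([p[:-2], p[1:-1], p[2:]])
    return np.median(stacked, axis=0)


def median_filter3(stream: SignalStream) -> SignalStream:
    """Order-3 running median per axis with edge replication.

    Removes isolated impulsive spikes; a length-1 stream is returned
    unchanged.
    """
    out = np.column_stack([_medfilt3_1d(stream.samples[:, a]) for a in range(3)])
    return stream.with_samples(out)


def _movavg_1d(v: np.ndarray, width: int) -> np.ndarray:
    half = (width - 1) // 2
    p = np.pad(v, half, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(p, kernel, mode="valid")


def moving_average(stream: SignalStream, width: int = 5) -> SignalStream:
    """Centered moving-average smoother per axis with edge replication."""
    if width < 1 or width % 2 == 0:
        raise ValueError("moving-average width must be a positive odd integer")
    if width > len(stream):
        raise ValueError("moving-average width exceeds stream length")
    if width == 1:
        return stream.with_samples(stream.samples.copy())
    out = np.column_stack([_movavg_1d(stream.samples[:, a], width) for a in range(3)])
    return stream.with_samples(out)


def moving_average_causal(stream: SignalStream, width: int) -> SignalStream:
    """Causal (trailing) moving average; introduces a (width-1)/2-sample delay."""
    if width < 1 or width % 2 == 0:
        raise ValueError("moving-average width must be a positive odd integer")
    if width > len(stream):
        raise ValueError("moving-average width exceeds stream length")
    out = np.empty_like(stream.samples)
    for a in range(3):
        v = stream.samples[:, a]
        p = np.pad(v, (width - 1, 0), mode="edge")
        out[:, a] = np.convolve(p, np.ones(width) / width, mode="valid")
    return stream.with_samples(out)


def compensate_delay(stream: SignalStream, width: int, causal: bool = False) -> SignalStream:
    """Undo the group delay of a causal smoothing filter.

    A causal width-w moving average delays the signal by (w-1)/2
    samples; compensation advances by the same amount, replicating the
    final sample at the tail. With the default centered filter the
    delay is zero and this is the identity.
    """
    if not causal or width <= 1:
        return stream.with_samples(stream.samples.copy())
    shift = (width - 1) // 2
    out = np.empty_like(stream.samples)
    out[: len(stream) - shift] = stream.samples[shift:]
    out[len(stream) - shift :] = stream.samples[-1]
    return stream.with_samples(out)


def axis_extremes(stream: SignalStream) -> list[tuple[float, float]]:
    """Per-axis (min, max) pairs, the normalization 'extremes'."""
    return [
        (float(stream.samples[:, a].min()), float(stream.samples[:, a].max()))
        for a in range(3)
    ]


def normalize_minmax(
    stream: SignalStream,
    extremes: list[tuple[float, float]] | None = None,
) -> SignalStream:
    """Affine min-max normalization of each axis to [0, 1].

    With ``extremes`` absent they are computed from the stream itself
    (the training pass); stored training extremes are applied to test
    streams, clamping out-of-range values into [0, 1]. A constant axis
    maps to all zeros with a logged warning.
    """
    ext = extremes if extremes is not None else axis_extremes(stream)
    out = np.empty_like(stream.samples)
    for a, (lo, hi) in enumerate(ext):
        if lo > hi:
            raise ValueError(f"axis {a} extremes have min {lo} > max {hi}")
        v = stream.samples[:, a]
        if hi == lo:
            log.warning("axis %d is constant under its extremes; mapped to zeros", a)
            out[:, a] = 0.0
        else:
            out[:, a] = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return stream.with_samples(out)


def frame(
    stream: SignalStream,
    window_seconds: float,
    overlap_ratio: float,
) -> list[WindowFrame]:
    """Split a stream into overlapped fixed-length windows.

    Window length W = round(window_seconds * rate); step =
    max(1, floor(W * (1 - overlap_ratio))). The trailing partial window
    is discarded, so the count is floor((N - W) / step) + 1 for N >= W
    and 0 otherwise.
    """
    if not 0.0 <= overlap_ratio < 1.0:
        raise ValueError("overlap_ratio must be in [0, 1)")
    w = int(round(window_seconds * stream.sampling_rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    n = len(stream)
    if n < w:
        return []
    step = max(1, int(np.floor(w * (1.0 - overlap_ratio))))
    frames = []
    for start in range(0, n - w + 1, step):
        frames.append(
            WindowFrame(
                axes=stream.samples[start : start + w].copy(),
                start_index=start,
                sampling_rate=stream.sampling_rate,
                label=stream.activity_label,
                sensor_kind=stream.sensor_kind,
                placement=stream.placement,
                subject_id=stream.subject_id,
            )
        )
    return frames


def preprocess_stream(
    stream: SignalStream,
    ma_width: int = 5,
    causal: bool = False,
    extremes: list[tuple[float, float]] | None = None,
) -> SignalStream:
    """Full denoising pass: median filter, smoothing, delay compensation,
    min-max normalization."""
    s = median_filter3(stream)
    if causal:
        s = moving_average_causal(s, ma_width)
        s = compensate_delay(s, ma_width, causal=True)
    else:
        s = moving_average(s, ma_width)
    return normalize_minmax(s, extremes)
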