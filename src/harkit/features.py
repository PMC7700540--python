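"""Multi-fused feature bank: time, frequency, and acoustic descriptors per frame.

Per axis (x, y, z): mean, median, histogram mode, sample standard
deviation and variance, min, max, quartile-gated negative/positive
peaks, zero-crossing rate (on the mean-removed series), signal energy,
fundamental frequency and its phase angle, normalized spectral entropy,
and nine Hilbert descriptors of the first three empirical-mode-
decomposition IMFs (energy fraction, mean instantaneous amplitude,
mean instantaneous frequency). Per frame: mean vector magnitude,
signal magnitude area, and the three pairwise axis correlations.
That is 22 distinct feature kinds and a 74-long vector per frame
(3 axes x 23 values + 5 frame-level values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert
from scipy.signal.windows import hann

from .types import WindowFrame, FeatureVector, RunConfig

log = logging.getLogger(__name__)

# EMD constants: canonical sifting parameters
EMD_SD_THRESHOLD = 0.2
EMD_MAX_SIFTS = 10
EMD_MAX_IMFS = 8
HHT_N_IMFS = 3


@dataclass(frozen=True)
class SpectralBand:
    """A frequency band [f1, f2] with its bin count for entropy scaling."""

    f1: float
    f2: float
    n_band: int

    def __post_init__(self) -> None:
        if not 0 <= self.f1 < self.f2:
            raise ValueError("band must satisfy 0 <= f1 < f2")
        if self.n_band < 2:
            raise ValueError("band must contain at least 2 bins")


@dataclass
class IMFSet:
    """Intrinsic mode functions plus monotone residue; sums back to the input."""

    imfs: list[np.ndarray]
    residue: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


# ---------------------------------------------------------------------------
# time-domain features


def mean_feature(series: np.ndarray) -> float:
    return float(np.mean(series))


def median_feature(series: np.ndarray) -> float:
    return float(np.median(series))


def min_feature(series: np.ndarray) -> float:
    return float(np.min(series))


def max_feature(series: np.ndarray) -> float:
    return float(np.max(series))


def std_feature(series: np.ndarray) -> float:
    """Sample standard deviation with the n-1 denominator."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("standard deviation needs at least 2 samples (n-1 denominator)")
    return float(np.std(series, ddof=1))


def variance_feature(series: np.ndarray) -> float:
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("variance needs at least 2 samples (n-1 denominator)")
    return float(np.var(series, ddof=1))


def mode_feature(series: np.ndarray) -> float:
    """Center of the most populated of 10 equal bins over [min, max].

    Leftmost bin wins ties; a constant series returns the constant.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = float(series.min()), float(series.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(series, bins=10, range=(lo, hi))
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2.0)


def zero_crossing_rate(series: np.ndarray) -> float:
    """Sign changes between consecutive nonzero-signed samples over (W - 1).

    Callers pass the mean-removed axis signal: after min-max
    normalization all raw values are non-negative and the raw rate
    would be identically zero; mean removal restores the negative-to-
    positive interchange the feature measures.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("zero-crossing rate needs at least 2 samples")
    nz = series[series != 0.0]
    if len(nz) < 2:
        return 0.0
    signs = np.sign(nz)
    crossings = int(np.sum(signs[1:] != signs[:-1]))
    return crossings / (len(series) - 1)


def peak_features(series: np.ndarray) -> tuple[float, float]:
    """(negative peak, positive peak) gated by the quartiles.

    Negative peak: minimum over samples strictly below Q1; positive
    peak: maximum over samples strictly above Q3 (linear-interpolation
    quartiles). Empty subsets fall back to the global min / max.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 4:
        raise ValueError("peak features need at least 4 samples")
    q1, q3 = np.quantile(series, [0.25, 0.75])
    below = series[series < q1]
    above = series[series > q3]
    neg = float(below.min()) if len(below) else float(series.min())
    pos = float(above.max()) if len(above) else float(series.max())
    return neg, pos


def signal_energy(series: np.ndarray) -> float:
    """Mean squared amplitude."""
    series = np.asarray(series, dtype=float)
    return float(np.mean(series**2))


def signal_magnitude_mean(frame: WindowFrame) -> float:
    """Mean over samples of the instantaneous vector magnitude
    sqrt(x_i^2 + y_i^2 + z_i^2)."""
    return float(np.mean(np.linalg.norm(frame.axes, axis=1)))


def signal_magnitude_area(frame: WindowFrame, absolute: bool = False) -> float:
    """Signed triple axis sum (sum x + sum y + sum z) normalized by the
    window length, so the feature scale is window-length invariant.

    ``absolute=True`` sums absolute values instead (the common SMA
    convention); the signed form is the default.
    """
    a = np.abs(frame.axes) if absolute else frame.axes
    return float(a.sum() / len(frame))


def correlation_features(frame: WindowFrame) -> tuple[float, float, float]:
    """Pearson correlations (r_xy, r_yz, r_zx); 0 with a warning when an
    axis is constant."""

    def corr(u: np.ndarray, v: np.ndarray) -> float:
        if np.std(u) == 0.0 or np.std(v) == 0.0:
            log.warning("constant axis in correlation; returning 0")
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    return (
        corr(frame.x, frame.y),
        corr(frame.y, frame.z),
        corr(frame.z, frame.x),
    )


# ---------------------------------------------------------------------------
# frequency-domain features


def _hann_periodogram(series: np.ndarray) -> np.ndarray:
    w = hann(len(series), sym=False)
    return np.abs(np.fft.rfft(series * w)) ** 2


def fundamental_frequency(series: np.ndarray, rate: float) -> float:
    """Hann-periodogram argmax excluding the DC bin, in Hz.

    A constant series has no oscillation and returns 0 by convention.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 4:
        raise ValueError("fundamental frequency needs at least 4 samples")
    if np.ptp(series) == 0.0:
        return 0.0
    power = _hann_periodogram(series)
    k = 1 + int(np.argmax(power[1:]))
    return k * rate / len(series)


def phase_angle(series: np.ndarray, rate: float) -> float:
    """Argument of the raw FFT coefficient at the fundamental bin, in
    (-pi, pi]; 0 for a constant series."""
    series = np.asarray(series, dtype=float)
    if len(series) < 4:
        raise ValueError("phase angle needs at least 4 samples")
    if np.ptp(series) == 0.0:
        return 0.0
    power = _hann_periodogram(series)
    k = 1 + int(np.argmax(power[1:]))
    coef = np.fft.rfft(series)[k]
    return float(np.angle(coef))


def spectral_entropy(
    series: np.ndarray, rate: float, band: SpectralBand | None = None
) -> float:
    """Shannon entropy of the normalized PSD over a band, scaled to [0, 1]
    by log of the band's bin count.

    The default band is (0, Nyquist], i.e. every positive-frequency
    bin. Zero-power bins contribute 0; an all-zero series returns 0
    with a warning.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 4:
        raise ValueError("spectral entropy needs at least 4 samples")
    psd = np.abs(np.fft.rfft(series)) ** 2
    freqs = np.fft.rfftfreq(len(series), d=1.0 / rate)
    if band is None:
        mask = freqs > 0.0
        n_band = int(mask.sum())
    else:
        mask = (freqs > band.f1) & (freqs <= band.f2)
        n_band = band.n_band
    p = psd[mask]
    total = p.sum()
    if total == 0.0:
        log.warning("zero-power spectrum; spectral entropy set to 0")
        return 0.0
    p = p / total
    nz = p[p > 0.0]
    return float(-np.sum(nz * np.log(nz)) / np.log(n_band))


# ---------------------------------------------------------------------------
# empirical mode decomposition + Hilbert descriptors


def _local_extrema(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior maxima and minima (plateau midpoints count once)."""
    d = np.diff(h)
    # propagate the previous nonzero slope through flats
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    turn = np.diff(s)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _envelope(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray | None:
    """Cubic-spline envelope through extrema with mirror boundary extension."""
    if len(idx) < 2:
        return None
    k = min(2, len(idx))
    left_t = -idx[:k][::-1]
    left_v = values[idx[:k]][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = values[idx[-k:]][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, values[idx], right_v])
    # mirrored points can coincide with originals when an extremum sits at the edge
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    if len(t) < 2:
        return None
    return CubicSpline(t, v)(np.arange(n))


def emd(series: np.ndarray) -> IMFSet:
    """Empirical mode decomposition by standard sifting.

    Upper/lower cubic-spline envelopes through interior maxima/minima
    with mirror boundary extension; each sift subtracts the envelope
    mean. An IMF is accepted when the Cauchy SD criterion drops below
    0.2 or after 10 sifts; decomposition stops when the residue is
    monotone (no interior extrema pair) or 8 IMFs have been extracted.
    The residue is the exact remainder, so IMFs + residue reconstruct
    the input to machine precision.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 8:
        raise ValueError("EMD needs at least 8 samples")
    n = len(series)
    residue = series.copy()
    imfs: list[np.ndarray] = []

    while len(imfs) < EMD_MAX_IMFS:
        maxima, minima = _local_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break  # monotone-enough residue
        h = residue.copy()
        for _ in range(EMD_MAX_SIFTS):
            maxima, minima = _local_extrema(h)
            upper = _envelope(maxima, h, n)
            lower = _envelope(minima, h, n)
            if upper is None or lower is None:
                break
            m = (upper + lower) / 2.0
            h_new = h - m
            denom = float(np.sum(h**2))
            if denom == 0.0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < EMD_SD_THRESHOLD:
                break
        imfs.append(h)
        residue = residue - h

    return IMFSet(imfs=imfs, residue=residue)


def _instantaneous(imf: np.ndarray, rate: float) -> tuple[float, float]:
    """(mean instantaneous amplitude, mean instantaneous frequency) of one IMF.

    Frequency is the unwrapped analytic-signal phase difference,
    averaged over interior samples only (a 10% margin at each end)
    to suppress Hilbert edge effects.
    """
    analytic = hilbert(imf)
    amp = float(np.mean(np.abs(analytic)))
    phase = np.unwrap(np.angle(analytic))
    dphi = np.diff(phase)
    margin = max(1, len(dphi) // 10)
    interior = dphi[margin:-margin] if len(dphi) > 2 * margin else dphi
    freq = float(np.mean(interior) * rate / (2.0 * np.pi))
    return amp, freq


def hht_features(series: np.ndarray, rate: float) -> list[float]:
    """Nine Hilbert-Huang descriptors: for each of the first 3 IMFs the
    energy fraction, mean instantaneous amplitude, and mean
    instantaneous frequency, zero-filled when fewer IMFs exist."""
    series = np.asarray(series, dtype=float)
    total_energy = float(np.sum(series**2))
    decomp = emd(series) if len(series) >= 8 else IMFSet([], series.copy())
    out: list[float] = []
    for i in range(HHT_N_IMFS):
        if i < len(decomp.imfs) and total_energy > 0.0:
            imf = decomp.imfs[i]
            energy_frac = float(np.sum(imf**2)) / total_energy
            amp, freq = _instantaneous(imf, rate)
            out.extend([energy_frac, amp, freq])
        else:
            out.extend([0.0, 0.0, 0.0])
    return out


# ---------------------------------------------------------------------------
# assembly

_AXIS_SCALARS = [
    ("mean", "time"),
    ("median", "time"),
    ("mode", "time"),
    ("std", "time"),
    ("var", "time"),
    ("min", "time"),
    ("max", "time"),
    ("neg_peak", "time"),
    ("pos_peak", "time"),
    ("zcr", "acoustic"),
    ("energy", "time"),
    ("fund_freq", "frequency"),
    ("phase", "frequency"),
    ("spec_entropy", "acoustic"),
]

_HHT_NAMES = [
    f"hht_imf{i + 1}_{kind}"
    for i in range(HHT_N_IMFS)
    for kind in ("energy", "amp", "freq")
]

_FRAME_SCALARS = [
    ("mag_mean", "time"),
    ("sma", "time"),
    ("corr_xy", "time"),
    ("corr_yz", "time"),
    ("corr_zx", "time"),
]


def feature_registry() -> tuple[list[str], list[str]]:
    """The fixed (names, group tags) ordering of the full feature vector."""
    names: list[str] = []
    groups: list[str] = []
    for axis in ("x", "y", "z"):
        for stem, grp in _AXIS_SCALARS:
            names.append(f"{axis}_{stem}")
            groups.append(grp)
        for stem in _HHT_NAMES:
            names.append(f"{axis}_{stem}")
            groups.append("acoustic")
    for stem, grp in _FRAME_SCALARS:
        names.append(stem)
        groups.append(grp)
    return names, groups


def _axis_features(series: np.ndarray, rate: float) -> list[float]:
    neg, pos = peak_features(series)
    centered = series - np.mean(series)
    vals = [
        mean_feature(series),
        median_feature(series),
        mode_feature(series),
        std_feature(series),
        variance_feature(series),
        min_feature(series),
        max_feature(series),
        neg,
        pos,
        zero_crossing_rate(centered),
        signal_energy(series),
        fundamental_frequency(series, rate),
        phase_angle(series, rate),
        spectral_entropy(series, rate),
    ]
    vals.extend(hht_features(series, rate))
    return vals


def extract_all(frame: WindowFrame, config: RunConfig | None = None) -> FeatureVector:
    """The full multi-fused feature vector for one frame (74 values)."""
    config = config or RunConfig()
    values: list[float] = []
    for axis in (frame.x, frame.y, frame.z):
        values.extend(_axis_features(axis, frame.sampling_rate))
    values.append(signal_magnitude_mean(frame))
    values.append(signal_magnitude_area(frame, absolute=config.sma_absolute))
    values.extend(correlation_features(frame))
    names, groups = feature_registry()
    return FeatureVector(names=names, values=np.array(values), label=frame.label,
                         groups=groups)


def extract_table(frames, config: RunConfig | None = None) -> list[FeatureVector]:
    """Feature vectors for a list of frames."""
    return [extract_all(f, config) for f in frames]


def merge_sensor_vectors(
    vectors: list[FeatureVector], placements: list[str] | None = None
) -> FeatureVector:
    """Concatenate per-sensor feature vectors of one time window,
    prefixing names with each sensor's placement (multi-sensor fusion)."""
    names: list[str] = []
    values: list[float] = []
    groups: list[str] = []
    label = vectors[0].label
    for i, v in enumerate(vectors):
        prefix = placements[i] if placements else f"s{i}"
        names.extend(f"{prefix}_{n}" for n in v.names)
        values.extend(v.values)
        groups.extend(v.groups or [""] * len(v))
    return FeatureVector(names=names, values=np.array(values), label=label, groups=groups)
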