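"""Synthetic labeled triaxial inertial streams for testing the full pipeline.

Each activity class is a harmonic oscillation per axis (class-specific
base frequency and harmonic content, distinct per-axis amplitudes and
phase offsets) riding on a constant gravity offset, plus Gaussian noise
and Poisson-timed impulsive spikes emulating abrupt-movement artifacts
that the median filter is meant to remove. No biomechanical realism is
attempted; the generator only provides controllable, learnable class
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SignalStream, RunConfig

# fixed per-axis phase offsets so axes are not trivially identical
AXIS_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass
class ActivityClassSpec:
    """Generative parameters for one activity class."""

    name: str
    base_frequency: float  # Hz
    harmonics: list[tuple[float, float]] = field(default_factory=lambda: [(1.0, 1.0)])
    axis_amplitudes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gravity_offset: tuple[float, float, float] = (0.0, 0.0, 9.81)
    noise_sd: float = 0.0
    spike_rate: float = 0.0  # events per second
    spike_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.base_frequency < 0:
            raise ValueError("base_frequency must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")


def generate_stream(
    spec: ActivityClassSpec,
    duration: float,
    rate: float = 100.0,
    seed: int = 0,
) -> SignalStream:
    """Generate one labeled stream of ``duration`` seconds at ``rate`` Hz.

    Deterministic given (spec, duration, rate, seed). Per axis a:
    ``g_a + A_a * sum_k r_k sin(2 pi k f t + phi_a) + N(0, sd) + spikes``.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = int(round(duration * rate))
    if n < 1:
        raise ValueError("duration * rate must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate

    samples = np.empty((n, 3))
    for a in range(3):
        sig = np.full(n, spec.gravity_offset[a], dtype=float)
        osc = np.zeros(n)
        for mult, rel_amp in spec.harmonics:
            osc += rel_amp * np.sin(
                2.0 * np.pi * mult * spec.base_frequency * t + AXIS_PHASES[a]
            )
        sig += spec.axis_amplitudes[a] * osc
        samples[:, a] = sig

    if spec.noise_sd > 0:
        samples += rng.normal(0.0, spec.noise_sd, size=(n, 3))
    if spec.spike_rate > 0 and spec.spike_magnitude != 0:
        n_spikes = rng.poisson(spec.spike_rate * duration)
        if n_spikes > 0:
            idx = rng.integers(0, n, size=n_spikes)
            axis = rng.integers(0, 3, size=n_spikes)
            sign = rng.choice([-1.0, 1.0], size=n_spikes)
            samples[idx, axis] += sign * spec.spike_magnitude

    return SignalStream(
        samples=samples,
        sampling_rate=rate,
        activity_label=spec.name,
    )


def generate_dataset(
    specs: list[ActivityClassSpec],
    n_windows_per_class: int,
    config: RunConfig | None = None,
    seed: int = 0,
) -> list[SignalStream]:
    """Generate one long stream per class, sized to yield at least
    ``n_windows_per_class`` frames at the configured window/overlap.

    Per-class draws use independent sub-seeds derived deterministically
    from ``seed``, so adding a class never perturbs the others.
    """
    config = config or RunConfig()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names in specs")
    if len(specs) < 2:
        raise ValueError("need at least 2 activity class specs")

    w = int(round(config.window_seconds * config.sampling_rate))
    step = max(1, int(np.floor(w * (1.0 - config.overlap_ratio))))
    n_samples = w + (n_windows_per_class - 1) * step
    duration = n_samples / config.sampling_rate

    children = np.random.SeedSequence(seed).spawn(len(specs))
    sub_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return [
        generate_stream(spec, duration, config.sampling_rate, sub)
        for spec, sub in zip(specs, sub_seeds)
    ]


def default_preset() -> list[ActivityClassSpec]:
    """The shipped 6-class preset.

    Adjacent base frequencies 0.4 Hz apart in the gait band, distinct
    per-axis amplitudes and gravity orientations, overlapping noise
    levels — separable but not trivially so.
    """
    return [
        ActivityClassSpec(
            name="sit-like",
            base_frequency=0.8,
            harmonics=[(1.0, 1.0)],
            axis_amplitudes=(0.15, 0.10, 0.12),
            gravity_offset=(0.5, 9.7, 1.0),
            noise_sd=0.15,
            spike_rate=0.02,
            spike_magnitude=1.0,
        ),
        ActivityClassSpec(
            name="stand-like",
            base_frequency=1.2,
            harmonics=[(1.0, 1.0), (2.0, 0.2)],
            axis_amplitudes=(0.12, 0.18, 0.10),
            gravity_offset=(0.0, 0.3, 9.8),
            noise_sd=0.15,
            spike_rate=0.02,
            spike_magnitude=1.0,
        ),
        ActivityClassSpec(
            name="ascend-like",
            base_frequency=1.6,
            harmonics=[(1.0, 1.0), (2.0, 0.5)],
            axis_amplitudes=(1.2, 2.0, 0.9),
            gravity_offset=(1.5, 9.2, 2.0),
            noise_sd=0.25,
            spike_rate=0.1,
            spike_magnitude=3.0,
        ),
        ActivityClassSpec(
            name="descend-like",
            base_frequency=2.0,
            harmonics=[(1.0, 1.0), (2.0, 0.4), (3.0, 0.15)],
            axis_amplitudes=(1.5, 2.4, 1.1),
            gravity_offset=(1.2, 9.0, 2.5),
            noise_sd=0.3,
            spike_rate=0.15,
            spike_magnitude=3.5,
        ),
        ActivityClassSpec(
            name="walk-like",
            base_frequency=2.4,
            harmonics=[(1.0, 1.0), (2.0, 0.6), (3.0, 0.2)],
            axis_amplitudes=(2.0, 3.0, 1.5),
            gravity_offset=(0.8, 9.5, 1.5),
            noise_sd=0.3,
            spike_rate=0.2,
            spike_magnitude=4.0,
        ),
        ActivityClassSpec(
            name="jog-like",
            base_frequency=2.8,
            harmonics=[(1.0, 1.0), (2.0, 0.7), (3.0, 0.3)],
            axis_amplitudes=(3.5, 5.0, 2.5),
            gravity_offset=(1.0, 9.3, 1.8),
            noise_sd=0.4,
            spike_rate=0.3,
            spike_magnitude=6.0,
        ),
    ]


def make_informative_table(
    n_informative: int = 5,
    n_noise: int = 30,
    n_per_class: int = 100,
    n_classes: int = 2,
    effect: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Feature table with class-separated informative columns and pure-noise
    columns; returns (X, y, informative_column_indices).

    Informative column j for class c has mean ``effect * (c + j mod 2)``
    alternating so no single column separates all classes alone.
    """
    rng = np.random.default_rng(seed)
    n_features = n_informative + n_noise
    cols = rng.permutation(n_features)
    informative = sorted(int(c) for c in cols[:n_informative])
    X = rng.normal(0.0, 1.0, size=(n_per_class * n_classes, n_features))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for rank, j in enumerate(informative):
        shift = effect * (1 if rank % 2 == 0 else -1)
        X[:, j] += shift * y
    return X, y.astype(str), informative
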