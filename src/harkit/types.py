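"""Core containers: raw records, streams, frames, feature vectors, run config."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

SENSOR_KINDS = ("accelerometer", "gyroscope", "magnetometer")
PLACEMENTS = ("wrist", "chest", "thigh", "waist", "pocket", "unspecified")


@dataclass(frozen=True)
class RawRecord:
    """One parsed sensor sample: subject, label, device timestamp, triaxial value."""

    subject_id: str
    activity_label: str
    timestamp: int
    x: float
    y: float
    z: float


@dataclass
class SignalStream:
    """A uniformly sampled triaxial sensor series with metadata.

    ``samples`` is an (N, 3) float array; columns are the x, y, z axes in
    sensor units (m/s^2, rad/s or uT depending on ``sensor_kind``; units
    are metadata only and never converted).
    """

    samples: np.ndarray
    sampling_rate: float
    sensor_kind: str = "accelerometer"
    placement: str = "unspecified"
    subject_id: str = ""
    activity_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (N, 3) array")
        if len(self.samples) < 1:
            raise ValueError("stream must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stream samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]

    def with_samples(self, samples: np.ndarray) -> "SignalStream":
        """Copy of this stream with new sample values, same metadata."""
        return SignalStream(
            samples=samples,
            sampling_rate=self.sampling_rate,
            sensor_kind=self.sensor_kind,
            placement=self.placement,
            subject_id=self.subject_id,
            activity_label=self.activity_label,
        )


@dataclass
class WindowFrame:
    """A fixed-length segment of a stream; the unit of feature extraction."""

    axes: np.ndarray  # (W, 3)
    start_index: int
    sampling_rate: float
    label: str | None = None
    sensor_kind: str = "accelerometer"
    placement: str = "unspecified"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[1] != 3:
            raise ValueError("axes must be a (W, 3) array")
        if len(self.axes) < 2:
            raise ValueError("frame length must be >= 2")
        if not np.all(np.isfinite(self.axes)):
            raise ValueError("frame values must be finite")

    def __len__(self) -> int:
        return len(self.axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


@dataclass
class FeatureVector:
    """Named, ordered scalar features for one frame, plus its label."""

    names: list[str]
    values: np.ndarray
    label: str | None = None
    groups: list[str] = field(default_factory=list)  # time | frequency | acoustic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GAConfig:
    """Genetic-algorithm settings for feature selection.

    Mutation rate 0.05 is the method's published value; the remaining
    knobs (population, tournament, crossover probability, elitism,
    patience) are standard GA machinery.
    """

    population_size: int = 30
    max_generations: int = 50
    crossover_prob: float = 0.8
    mutation_rate: float = 0.05
    tournament_size: int = 3
    elitism: int = 1
    patience: int = 10
    rf_estimators: int = 100  # trees in the random-forest half of the fitness
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    sampling_rate: float = 100.0
    window_seconds: float = 2.0
    overlap_ratio: float = 0.6
    ma_width: int = 5
    sma_absolute: bool = False
    causal_smoothing: bool = False
    similarity: str = "cosine"  # cosine | euclidean
    split_fraction: float = 0.7
    seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_ratio < 1.0:
            raise ValueError("overlap_ratio must be in [0, 1)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if isinstance(self.ga, dict):
            self.ga = GAConfig(**self.ga)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a RunConfig from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def streams_to_frames(streams: Sequence[SignalStream], config: RunConfig):
    """Frame every stream with the configured window/overlap (convenience)."""
    from .preprocess import frame

    out = []
    for s in streams:
        out.extend(frame(s, config.window_seconds, config.overlap_ratio))
    return out
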