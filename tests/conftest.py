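import numpy as np
import pytest

from harkit.types import SignalStream, WindowFrame, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_frame(rng):
    return WindowFrame(
        axes=rng.normal(0.0, 1.0, size=(128, 3)),
        start_index=0,
        sampling_rate=100.0,
        label="test",
    )


@pytest.fixture
def random_stream(rng):
    return SignalStream(
        samples=rng.normal(0.0, 1.0, size=(500, 3)),
        sampling_rate=100.0,
        activity_label="noise",
    )


@pytest.fixture
def config():
    return RunConfig()


def make_stream(values, rate=100.0, label=None):
    """Helper: stream whose x axis is `values`, y and z zero-ish ramps."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    samples = np.column_stack([values, np.linspace(0, 1, n), np.zeros(n)])
    return SignalStream(samples=samples, sampling_rate=rate, activity_label=label)
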