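import numpy as np
import pytest

from aeronose.aero import ActivationBins, EncodingConfig
from aeronose.recording import RawRecording
from aeronose.synthetic import SimulationConfig, generate_dataset


@pytest.fixture
def small_config():
    """A fast-but-nontrivial study: 3 classes, 12 sensors, 5 replicates."""
    return SimulationConfig(
        n_classes=3, n_sensors=12, replicates_per_class=5, seed=7
    )


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


def make_recording(values, sampling_rate=1.0, phase_boundaries=None, **kw):
    values = np.asarray(values, dtype=float)
    if phase_boundaries is None:
        T = values.shape[0]
        b = T // 4
        phase_boundaries = (0, b, 3 * b, 3 * b, T)
    return RawRecording(
        sensor_ids=list(range(1, values.shape[1] + 1)),
        values=values,
        sampling_rate=sampling_rate,
        phase_boundaries=phase_boundaries,
        **kw,
    )


def make_bins(indices, config=None):
    if config is None:
        config = EncodingConfig(n_bits=2, timepoints=10, sensor_ids=(1, 2))
    return ActivationBins(bins=frozenset(indices), config=config)


@pytest.fixture
def tiny_encoding():
    return EncodingConfig(n_bits=2, timepoints=10, sensor_ids=(1, 2))
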