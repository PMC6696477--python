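import numpy as np
import pytest

from aossom.calibrate import Dataset
from aossom.features import extract_features, features_to_frame
from aossom.signal_io import PreprocessConfig, SensorRecording, preprocess
from aossom.split import kennard_stone, train_count
from aossom.synthetic import (SimulatorConfig, default_sensor_params,
                              simulate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def make_recording():
    """Factory for small valid recordings (10 channels, >= 201 samples)."""

    def _make(n=300, dt=0.1, vc=5.0, seed=0, sample_id="rec01", som=None):
        gen = np.random.default_rng(seed)
        channels = np.clip(gen.uniform(0.5, 4.5, size=(10, n)), 0, vc)
        return SensorRecording(sample_id=sample_id, channels=channels,
                               dt=dt, vc=vc, som_reference=som)

    return _make


@pytest.fixture(scope="session")
def noiseless_config():
    """Short-duration noiseless campaign: fast but structurally faithful."""
    return SimulatorConfig(n_samples=30, seed=11,
                           sensors=default_sensor_params(noise_sd=0.0),
                           duration=60.0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    """Feature table + KS split from a small noiseless simulation."""
    recordings, som = simulate_dataset(noiseless_config)
    cfg = PreprocessConfig(duration=noiseless_config.duration)
    tables = [extract_features(preprocess(r, cfg)) for r in recordings]
    frame = features_to_frame(tables, som=som)
    partition = kennard_stone(frame.drop(columns=["som_g_per_kg"]),
                              train_count(len(frame), 0.7))
    data = Dataset.from_dataframe(frame)
    return (data.subset(partition.train_ids),
            data.subset(partition.valid_ids))
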