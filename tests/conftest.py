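import numpy as np
import pytest

from microstates import EEGRecording, SimulationConfig, modified_kmeans, simulate_recording
from microstates.preprocess import average_reference, bandpass_filter, downsample
from microstates.synth import generate_templates


@pytest.fixture(scope="session")
def small_sim():
    """One moderate synthetic recording with known structure (64 ch, 60 s)."""
    cfg = SimulationConfig(n_channels=64, fs=125.0, duration_s=60.0, k_true=4, snr=2.0, seed=11)
    rec, gt = simulate_recording(cfg, subject="sim0")
    return cfg, rec, gt


@pytest.fixture(scope="session")
def preprocessed_sim(small_sim):
    cfg, rec, gt = small_sim
    r = average_reference(downsample(bandpass_filter(rec), 125.0))
    return cfg, r, gt


@pytest.fixture(scope="session")
def fitted_model(preprocessed_sim):
    from microstates.cluster import extract_peak_maps

    cfg, rec, gt = preprocessed_sim
    maps, _ = extract_peak_maps(rec)
    model = modified_kmeans(maps, cfg.k_true, n_restarts=15, seed=5)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(rng):
    """Small random average-referenced recording."""
    data = rng.normal(size=(8, 200))
    data -= data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=100.0)


@pytest.fixture(scope="session")
def orthogonal_templates():
    return generate_templates(4, 16, seed=0)
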