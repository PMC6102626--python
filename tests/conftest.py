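import numpy as np
import pytest

from botanicad import synth
from botanicad.traces import Trace


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default dataset shared across tests (read-only)."""
    return synth.generate_dataset(synth.GenerationConfig(), seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    return synth.GenerationConfig(
        noise_sd_frac=0.0, calib_noise_frac=0.0, fid_area_noise_frac=0.0,
        baseline_level=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return synth.generate_dataset(noiseless_config, seed=7)


def gaussian_trace(centers, sigmas, areas, t0=0.0, t1=10.0, dt=0.005,
                   baseline=0.0, noise_sd=0.0, seed=0, channel="CAD"):
    """Small helper to build analytic Gaussian traces for unit tests."""
    t = np.arange(t0, t1 + dt / 2, dt)
    y = np.full_like(t, float(baseline))
    for mu, sig, area in zip(centers, sigmas, areas):
        y += area / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return Trace(t, y, channel)
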