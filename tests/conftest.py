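import numpy as np
import pytest

from optoflow import (OpticalDensitySeries, SimulationConfig, default_layout,
                      intensity_to_od, simulate_recording)

FS = 3.9062


@pytest.fixture(scope="session")
def default_recording():
    rec, gt = simulate_recording(SimulationConfig(), seed=11)
    return rec, gt


@pytest.fixture(scope="session")
def default_od(default_recording):
    rec, _ = default_recording
    return intensity_to_od(rec)


@pytest.fixture()
def single_channel_layout():
    return default_layout(1, 0)


def make_od(x, fs=FS, layout=None):
    """Wrap a 1-D array as a one-channel, two-wavelength OD series."""
    layout = layout or default_layout(1, 0)
    arr = np.stack([np.asarray(x, float)] * 2, axis=1)[:, None, :]
    return OpticalDensitySeries(od=arr, fs=fs, layout=layout)


def lf_baseline(n, fs=FS, seed=0, noise_sd=5e-4):
    """Smooth low-frequency baseline + small noise (spike-test background)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    return (0.01 * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
            + noise_sd * rng.standard_normal(n)), rng
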