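import numpy as np
import pytest
from dataclasses import replace

import massnet as mn


@pytest.fixture(scope="session")
def small_connectome():
    """Small connected graph for fast network tests."""
    return mn.generate_connectome(
        mn.ConnectomeRecipe(n_regions=8, mean_degree=4, seed=3)
    )


@pytest.fixture(scope="session")
def short_cfg():
    """Reduced-duration configuration for fast simulation tests.

    2048 retained samples keep the spectral resolution at ~0.24 Hz, fine
    enough for peak-frequency checks.
    """
    return mn.NetworkConfig(duration_samples=2548, transient_samples=500)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Minimal run for determinism/round-trip checks (no spectra)."""
    return mn.NetworkConfig(duration_samples=400, transient_samples=100)


def tone(freq, n=4096, fs=500.0, amplitude=1.0, phase=0.0, bin_aligned=True):
    """Sinusoid; by default snapped to the nearest FFT bin to avoid leakage."""
    if bin_aligned:
        freq = round(freq * n / fs) * fs / n
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)
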