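import numpy as np
import pytest

from skinstrain import SimConfig, generate_sequence


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast deforming-tube sequence with noise-free targets."""
    cfg = SimConfig(n_frames=20, n_circumferential=12, n_axial=14,
                    n_markers=10, noise_sigma_mm=0.0, seed=7)
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Small sequence with the default 0.5 mm per-vertex Gaussian noise."""
    cfg = SimConfig(n_frames=20, n_circumferential=12, n_axial=14,
                    n_markers=10, noise_sigma_mm=0.5, seed=7)
    return generate_sequence(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
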