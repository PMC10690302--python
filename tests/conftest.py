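import numpy as np
import pytest

from flow4dsr import (
    BaseLearnerConfig,
    build_dataset,
    compartment_suite,
    make_pair,
    poiseuille_tube,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tube():
    """A mid-size Poiseuille tube phantom (aortic scale)."""
    return poiseuille_tube(
        radius_mm=8.0, length_mm=48.0, peak_velocity_cms=150.0,
        spacing_mm=1.25,
    )


@pytest.fixture(scope="session")
def hr_lr_pair(tube):
    """A noise-free HR/LR pair from the tube phantom."""
    return make_pair(tube, 0, snr_db=None, seed=0)


@pytest.fixture(scope="session")
def noisy_pair(tube):
    return make_pair(tube, 0, snr_db=15.0, seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """A small three-compartment patch dataset (seeded, ~100 patches)."""
    samples = []
    for comp in ("cardiac", "aortic", "cerebro"):
        samples += compartment_suite(comp, 4, seed=7, n_frames=2)
    return build_dataset(samples, seed=7)


@pytest.fixture(scope="session")
def tiny_config():
    return BaseLearnerConfig(
        channels=8, n_pre_blocks=1, n_post_blocks=1, seed=3
    )
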