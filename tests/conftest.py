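import numpy as np
import pytest

from pollenraman.simulate import (
    FoVDesign,
    SpectrumDesign,
    build_taxonomy_profiles,
    generate_dataset,
    generate_fov_image,
    separable_profiles,
)


@pytest.fixture(scope="session")
def small_design():
    """Compact axis for fast spectral tests (covers both analysis regions)."""
    return SpectrumDesign(n_channels=600, n_per_class=10, seed=7)


@pytest.fixture(scope="session")
def taxonomy_profiles():
    return build_taxonomy_profiles()


@pytest.fixture(scope="session")
def four_class_dataset():
    """Well-separated 4-class dataset with ground truth, shared across tests."""
    profiles = separable_profiles(4, amplitude_delta=0.5)
    design = SpectrumDesign(n_channels=600, n_per_class=40, noise_sd=0.02, seed=11)
    return generate_dataset(profiles, design, return_truth=True)


@pytest.fixture
def clean_fov():
    """Noise-free field of view with 5 well-separated disks."""
    design = FoVDesign(n_particles=5, min_separation=110.0, noise_sd=0.0, seed=3)
    return generate_fov_image(design)


def rng(seed=0):
    return np.random.default_rng(seed)
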