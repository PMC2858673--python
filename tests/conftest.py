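import numpy as np
import pytest

import stereopop as sp


@pytest.fixture(scope="session")
def small_config():
    """Reduced parameter grid: fast, but still spans orientation, frequency
    and phase disparity."""
    return sp.PopulationConfig(
        thetas=(-30.0, 0.0, 30.0, 90.0),
        freqs=(0.2, 0.0707),
        dphis=(-np.pi / 2, 0.0, np.pi / 2),
        dx_encs=tuple(range(-4, 5)),
    )


@pytest.fixture(scope="session")
def small_grid(small_config):
    return sp.make_population(small_config)


@pytest.fixture(scope="session")
def small_encoder(small_grid):
    return sp.EncoderBank(small_grid, shape=(61, 61))


@pytest.fixture(scope="session")
def small_bank(small_encoder):
    """Template bank for the reduced population over a +-4 px grid."""
    return sp.build_templates(
        small_encoder, grid=sp.default_grid(4), n_images=30, u=1.0, seed=3
    )


@pytest.fixture(scope="session")
def full_encoder():
    """The default 3150-unit population on 81x81 images."""
    return sp.EncoderBank()


@pytest.fixture(scope="session")
def ci_bank(full_encoder):
    """Full 21x21 template bank at the scaled-down (ci) profile: 50
    Gaussian-noise stereograms averaged per grid disparity.  Built once
    per session (a few CPU-minutes)."""
    return sp.build_profile_bank(full_encoder, profile="ci", u=1.0, seed=1)
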