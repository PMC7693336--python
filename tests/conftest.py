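import numpy as np
import pytest

from vesselflow.optics import AnnulusSpec, annulus_axial_profile
from vesselflow.scene import SceneConfig

# the paper-configuration annulus: outer NA 0.4, mask ratio 2.3/2.5,
# 920 nm in water
PAPER_SPEC = AnnulusSpec(na_outer=0.4, ratio=2.3 / 2.5, wavelength=0.92,
                         refractive_index=1.33)


@pytest.fixture(scope="session")
def paper_annulus():
    return PAPER_SPEC


@pytest.fixture(scope="session")
def bessel_profile():
    return annulus_axial_profile(PAPER_SPEC)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_config(**overrides) -> SceneConfig:
    """Small, fast default scene configuration for tests."""
    kwargs = dict(
        volume_size=(80.0, 40.0, 60.0),
        pixel_size=1.0,
        frame_rate=15.0,
        duration=2.0,
        n_pial=1,
        n_penetrating=1,
        n_capillaries=1,
        noise_photons=0.0,
        background=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


@pytest.fixture
def small_config():
    return make_config()
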