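import numpy as np
import pytest

from diamicro import (
    CalibratedImage,
    CrossSectionSpec,
    StriationSpec,
    generate_cross_section,
    generate_striation_image,
)


@pytest.fixture(scope="session")
def grating_2p5():
    """Noiseless full-field grating, 2.5 um period at 0.1 um/px."""
    spec = StriationSpec(period_um=2.5, gap_to_fiber_ratio=0.0,
                         fiber_width_um=80.0, seed=1)
    img, truth = generate_striation_image(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def fibered_image():
    """Noiseless gapped fiber image with known interstitial ratio."""
    spec = StriationSpec(period_um=2.5, seed=3)
    img, truth = generate_striation_image(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def section_40():
    """40-fiber cross-section, quarter of fibers centrally nucleated."""
    spec = CrossSectionSpec(n_fibers=40, csa_mean_um2=350.0,
                            central_nucleus_fraction=0.25,
                            macrophage_density_per_mm2=0.0,
                            pixel_size_um=0.25, image_shape=(512, 512), seed=2)
    img, truth = generate_cross_section(spec)
    return spec, img, truth


@pytest.fixture()
def white_noise_image():
    rng = np.random.default_rng(0)
    return CalibratedImage(rng.standard_normal((512, 512)).astype(np.float32), 0.1)
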