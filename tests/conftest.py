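import numpy as np
import pytest

from cd8pheno import deconvolve_stains, generate_slide


@pytest.fixture(scope="session")
def inflamed_slide():
    """One mid-size inflamed slide reused across detection/density tests."""
    return generate_slide("inflamed", width_px=1536, height_px=1536,
                          n_tumor_nests=2, tumor_coverage=0.45, seed=42)


@pytest.fixture(scope="session")
def inflamed_od(inflamed_slide):
    return deconvolve_stains(inflamed_slide.image, mpp=inflamed_slide.layout.mpp)


@pytest.fixture(scope="session")
def artifact_slide():
    """Slide with pigment + hemorrhage/necrosis patches (all six classes)."""
    return generate_slide("excluded", width_px=1024, height_px=1024,
                          n_tumor_nests=2, tumor_coverage=0.4,
                          artifact_fraction=0.06, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
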