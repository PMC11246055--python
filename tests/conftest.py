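import numpy as np
import pytest

from slidemae.fixtures import FixtureSpec, gen_outcomes, gen_store
from slidemae.model import RegionEncoder
from slidemae.store import SlideFeatureSet


@pytest.fixture(scope="session")
def toy_model():
    """Small deterministic encoder shared by read-only tests."""
    return RegionEncoder(d=16, L=2, H=4, n_max=6, dropout=0.0, seed=11)


@pytest.fixture()
def dense_slide():
    """Fully-foreground 6x6 slide with distinguishable per-cell features."""
    rows = cols = 6
    d = 8
    coords = np.array([(x, y) for y in range(rows) for x in range(cols)])
    feats = np.arange(rows * cols * d, dtype=np.float32).reshape(rows * cols, d)
    return SlideFeatureSet(
        slide_id="dense",
        magnification_tag="10x",
        patch_size_px=224,
        grid_shape=(rows, cols),
        features=feats,
        coords=coords,
    )


@pytest.fixture(scope="session")
def classification_cohort():
    spec = FixtureSpec(n_slides=24, outcome="classification", seed=3)
    cohort = gen_store(spec)
    return spec, cohort, gen_outcomes(spec, cohort)


@pytest.fixture(scope="session")
def survival_cohort():
    spec = FixtureSpec(n_slides=24, outcome="survival", seed=5)
    cohort = gen_store(spec)
    return spec, cohort, gen_outcomes(spec, cohort)
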