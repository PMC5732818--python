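import numpy as np
import pytest

from ecrad.features.extract import extract_table
from ecrad.synthetic_cohort import SyntheticCohortSpec, TextureParams, generate_cohort


def small_spec(n_resp=6, n_nonresp=6, seed=11, **kw) -> SyntheticCohortSpec:
    """Reduced-scale cohort spec used across tests: same texture contrast as
    the full-scale defaults, smaller volumes for speed."""
    kw.setdefault("volume_shape", (48, 48, 16))
    kw.setdefault("tumor_radius_range", (6.0, 9.0))
    return SyntheticCohortSpec(n_responders=n_resp, n_nonresponders=n_nonresp,
                               seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def feature_tables(small_cohort):
    t1 = extract_table(small_cohort, observer=1)
    t2 = extract_table(small_cohort, observer=2)
    return t1, t2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_levels(rng, shape, n_levels, p_mask=0.85):
    """Random quantized array + random mask for matrix-builder checks."""
    levels = rng.integers(0, n_levels, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask.flat[0] = True
    return levels, mask
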