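import numpy as np
import pytest

from hfomics.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort reused by read-only tests."""
    spec = CohortSpec(n_mrna=200, n_lnc=60, n_mir=60, planted_edges=5,
                      planted_ffls=1, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study design (21 HF vs 9 control)."""
    return generate_cohort(CohortSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
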