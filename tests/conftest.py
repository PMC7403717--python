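import numpy as np
import pytest

from pulseratchet.synthetic import (
    control_cohort_params,
    gen_cohort,
    knockdown_cohort_params,
)


@pytest.fixture(scope="session")
def control_cohort():
    """Small control-like cohort: every cell ratchets and constricts."""
    traces, truth = gen_cohort(control_cohort_params(n_cells=40, seed=11))
    return traces, truth


@pytest.fixture(scope="session")
def knockdown_cohort():
    """Small knockdown-like cohort with the 50/44/6% class mixture."""
    traces, truth = gen_cohort(knockdown_cohort_params(n_cells=50, seed=12))
    return traces, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
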