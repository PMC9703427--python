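import numpy as np
import pytest
from hypothesis import settings

import statecast as sc

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for pipeline plumbing tests (not for power)."""
    cfg = sc.SimConfig(n_individuals=12, t_min=120, t_max=200, seed=11)
    return sc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_kept(small_cohort):
    kept, _ = sc.filter_cohort(small_cohort, 0.7, (1, 5))
    return kept


def make_individual(states, k_vars=4, seed=0, ident="T0000"):
    """Individual with given states and pure-noise monitors, for index tests."""
    states = np.asarray(states, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return sc.IndividualRecord(
        id=ident,
        monitors=rng.standard_normal((states.size, k_vars)),
        states=states,
        baseline=sc.BaselineRecord(sex="female", age=50.0, weight=70.0, height=170.0),
    )
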