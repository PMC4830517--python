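"""Shared fixtures: reference synthetic cohorts and fitted models.

Expensive joint fits are session-scoped so the acceptance checks and the
unit tests share them.
"""

import numpy as np
import pytest

import jmclaims as jm
from jmclaims.simulate import SimulationConfig, simulate_cohort

#: truth values for the reference portfolio regime (generator defaults)
TRUTH = {
    "beta0": 0.319,
    "beta1": 0.014,
    "sd_b0": 0.329,
    "sd_b1": 0.050,
    "sigma": 0.471,
    "alpha": 1.462,
    "gamma_sex": -4.648,
    "gamma_age0": 0.095,
    "gamma_sex_age0": 0.059,
}


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_subjects=500)


@pytest.fixture(scope="session")
def cohort500(default_config):
    return simulate_cohort(default_config, seed=7)


@pytest.fixture(scope="session")
def joint_fit_500(cohort500):
    return jm.fit_joint(cohort500, n_interior=2, maxiter=800)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(n_subjects=120), seed=5)


def make_subject(sid="s1", sex=1, age0=75.0, t_obs=6.0, delta=0, series=((0.0, 1), (1.0, 2))):
    """Subject from (t, count) pairs with y = log1p(count)."""
    records = [jm.LongitudinalRecord.from_count(t, c) for t, c in series]
    return jm.Subject(id=sid, sex=sex, age0=age0, t_obs=t_obs, delta=delta, records=records)


@pytest.fixture
def toy_subject():
    return make_subject()
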