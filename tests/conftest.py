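import numpy as np
import pytest

import addarm
from addarm import (
    NormalPrior,
    Stage1Observation,
    TrialDesign,
    equal_split,
    joint_predictive,
    make_plan,
)
from addarm.designs import ADD, NO_ADD


@pytest.fixture(scope="session")
def case():
    return addarm.case_study()


@pytest.fixture(scope="session")
def jp_add(case):
    return joint_predictive(case.design, case.plan_add, case.priors, case.obs)


@pytest.fixture(scope="session")
def jp_noadd(case):
    return joint_predictive(case.design, case.plan_noadd, case.priors, case.obs)


def random_problem(rng: np.random.Generator):
    """A random, valid decision problem (design, priors, obs, plans)."""
    K = int(rng.integers(1, 4))
    n1 = {k: int(rng.integers(20, 200)) for k in range(K + 1)}
    sigma2 = {k: float(rng.uniform(0.5, 5.0)) for k in range(K + 2)}
    alpha = float(rng.uniform(0.01, 0.1))
    N2 = int(rng.integers(60, 400))
    design = TrialDesign(K=K, n1=n1, sigma2=sigma2, alpha=alpha, N2=N2)
    priors = {
        k: NormalPrior(float(rng.uniform(-1.5, 2.0)), float(rng.uniform(0.3, 8.0)))
        for k in range(1, K + 2)
    }
    obs = Stage1Observation(
        xbar1={k: float(rng.uniform(-1.0, 2.0)) for k in range(K + 1)}
    )
    plan_noadd = make_plan(design, NO_ADD, equal_split(N2, K + 1))
    plan_add = make_plan(design, ADD, equal_split(N2, K + 2))
    return design, priors, obs, plan_add, plan_noadd
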