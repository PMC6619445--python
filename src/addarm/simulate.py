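"""Monte Carlo oracle and frequentist operating characteristics.

Two roles.  First, an independent simulation check on every analytic
quantity: expected utilities and rejection-pattern probabilities are
re-estimated by drawing contrast vectors from the joint predictive and
counting threshold exceedances.  Second, frequentist operating
characteristics of an add-arm policy: stage-one data are simulated under
fixed true means, the policy picks a plan (always add, never add, or the
expected-utility decision rule), stage two is simulated under the realised
plan, and the final weighted Wald tests are applied — yielding empirical
rejection rates, family-wise error rate and decision frequencies.  Because a
mid-trial change of per-arm totals can inflate the type-I error, this
estimate is the honest way to report the level of the adaptive procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .bayes import NormalPrior
from .designs import ADD, NO_ADD, Stage2Plan, TrialDesign
from .testing import JointPredictive, Stage1Observation
from .utilities import _check_kind, decide

__all__ = [
    "SimulationSettings",
    "OperatingCharacteristics",
    "mc_expected_utility",
    "mc_pattern_probability",
    "simulate_stage1",
    "frequentist_oc",
]

POLICIES = ("always_add", "never_add", "decision_rule")


@dataclass(frozen=True)
class SimulationSettings:
    """Replication count, root seed, policy and true means for simulations."""

    n_sims: int
    seed: int
    policy: str = "never_add"
    true_means: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Empirical rates from :func:`frequentist_oc`, with binomial SEs."""

    rejection_rate: Mapping[int, float]
    rejection_se: Mapping[int, float]
    fwer: float
    fwer_se: float
    decision_freq: Mapping[str, float]
    n_sims: int


def _draws(jp: JointPredictive, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multivariate_normal(jp.mean, jp.cov, size=n, method="svd")


def mc_expected_utility(
    jp: JointPredictive, kind: str, settings: SimulationSettings
) -> tuple[float, float]:
    """Monte Carlo estimate (mean, standard error) of an expected utility."""
    _check_kind(kind)
    rng = np.random.default_rng(settings.seed)
    rejected = _draws(jp, settings.n_sims, rng) > jp.thresholds
    u = rejected.sum(axis=1)
    if kind == "disjunctive":
        u = np.minimum(u, 1)
    est = float(u.mean())
    se = float(u.std(ddof=1) / math.sqrt(settings.n_sims)) if settings.n_sims > 1 else 0.0
    return est, se


def mc_pattern_probability(
    jp: JointPredictive, reject_set: Iterable[int], settings: SimulationSettings
) -> tuple[float, float]:
    """Monte Carlo estimate (mean, SE) of an exact rejection pattern."""
    reject = set(reject_set)
    if not reject <= set(range(jp.dim)):
        raise ValueError("reject_set outside hypothesis positions")
    rng = np.random.default_rng(settings.seed)
    rejected = _draws(jp, settings.n_sims, rng) > jp.thresholds
    target = np.isin(np.arange(jp.dim), list(reject))
    hit = (rejected == target).all(axis=1)
    est = float(hit.mean())
    se = float(hit.std(ddof=1) / math.sqrt(settings.n_sims)) if settings.n_sims > 1 else 0.0
    return est, se


def simulate_stage1(
    design: TrialDesign,
    priors: Mapping[int, NormalPrior] | None,
    settings: SimulationSettings,
    mode: str = "prior_predictive",
    rng: np.random.Generator | None = None,
) -> Stage1Observation:
    """Draw one set of stage-one sample means.

    ``prior_predictive`` draws each experimental mean effect from its prior
    and then the sample mean around it; ``fixed_means`` uses
    ``settings.true_means``.  The control mean is always drawn around its
    true value (0 unless ``true_means`` says otherwise).  Pass ``rng`` to
    draw repeatedly from one stream; otherwise the settings seed is used.
    """
    if mode not in ("prior_predictive", "fixed_means"):
        raise ValueError("mode must be 'prior_predictive' or 'fixed_means'")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    xbar: dict[int, float] = {}
    mu0 = 0.0
    if settings.true_means is not None:
        mu0 = settings.true_means.get(0, 0.0)
    xbar[0] = mu0 + rng.normal() * math.sqrt(design.sigma2[0] / design.n1[0])
    for k in range(1, design.K + 1):
        if mode == "prior_predictive":
            if priors is None or k not in priors:
                raise ValueError(f"prior_predictive mode needs a prior for arm {k}")
            mu = priors[k].mean + rng.normal() * math.sqrt(priors[k].variance)
        else:
            if settings.true_means is None or k not in settings.true_means:
                raise ValueError(f"fixed_means mode needs a true mean for arm {k}")
            mu = settings.true_means[k]
        xbar[k] = mu + rng.normal() * math.sqrt(design.sigma2[k] / design.n1[k])
    return Stage1Observation(xbar1=xbar)


def _final_tests(
    design: TrialDesign,
    plan: Stage2Plan,
    xbar1: np.ndarray,
    xbar2: Mapping[int, np.ndarray],
) -> np.ndarray:
    """Rejection indicators, shape (n_sims, num_hypotheses)."""
    n01, n02 = design.n1[0], plan.n2[0]
    n0 = n01 + n02
    w01, w02 = n01 / n0, n02 / n0
    sig0 = design.sigma2[0]
    control = w01 * xbar1[0] + w02 * xbar2[0]
    cols = []
    for k in range(1, design.K + 1):
        nk1, nk2 = design.n1[k], plan.n2[k]
        nk = nk1 + nk2
        stat = (
            (nk1 / nk) * xbar1[k] + (nk2 / nk) * xbar2[k] - control
        ) / math.sqrt(design.sigma2[k] / nk + sig0 / n0)
        cols.append(stat > plan.boundary)
    if plan.decision == ADD:
        k = design.new_arm
        stat = (xbar2[k] - xbar2[0]) / math.sqrt(
            design.sigma2[k] / plan.n2[k] + sig0 / n02
        )
        cols.append(stat > plan.boundary)
    return np.column_stack(cols)


def frequentist_oc(
    design: TrialDesign,
    priors: Mapping[int, NormalPrior],
    plan_add: Stage2Plan,
    plan_noadd: Stage2Plan,
    kind: str,
    settings: SimulationSettings,
    epsilon: float = 0.01,
) -> OperatingCharacteristics:
    """Operating characteristics of an add-arm policy under fixed true means.

    Per replicate: simulate stage-one means at the true effects, let the
    policy choose the plan, simulate stage two at the true effects under the
    realised allocations, and apply the realised rejection rules.  Stage-two
    data are drawn from sampling distributions only — priors enter solely
    through the decision rule.  An ``indifferent`` verdict is resolved as
    ``no_add`` (the status-quo action).

    Returns per-hypothesis rejection rates (keyed by arm, the new arm
    counted only over replicates where it was added), the rate of at least
    one rejection, and decision frequencies.
    """
    _check_kind(kind)
    if settings.true_means is None:
        raise ValueError("frequentist_oc needs true_means in the settings")
    mu = {k: settings.true_means.get(k, 0.0) for k in range(design.K + 2)}
    n = settings.n_sims
    root = np.random.SeedSequence(settings.seed)
    rng1, rng2 = (np.random.default_rng(s) for s in root.spawn(2))

    # stage one, identical across policies for a given seed
    xbar1 = np.empty((design.K + 1, n))
    for k in range(design.K + 1):
        xbar1[k] = rng1.normal(mu[k], math.sqrt(design.sigma2[k] / design.n1[k]), n)

    if settings.policy == "always_add":
        add_mask = np.ones(n, dtype=bool)
    elif settings.policy == "never_add":
        add_mask = np.zeros(n, dtype=bool)
    else:
        add_mask = np.empty(n, dtype=bool)
        for i in range(n):
            obs = Stage1Observation(
                xbar1={k: float(xbar1[k, i]) for k in range(design.K + 1)}
            )
            out = decide(design, priors, obs, plan_add, plan_noadd, kind, epsilon)
            add_mask[i] = out.optimal == ADD

    def _stage2(plan: Stage2Plan, idx: np.ndarray) -> Mapping[int, np.ndarray]:
        return {
            k: rng2.normal(mu[k], math.sqrt(design.sigma2[k] / plan.n2[k]), idx.size)
            for k in plan.n2
        }

    reject = np.zeros((n, design.K + 1), dtype=bool)  # cols: arms 1..K, K+1
    for mask, plan in ((add_mask, plan_add), (~add_mask, plan_noadd)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        res = _final_tests(design, plan, xbar1[:, idx], _stage2(plan, idx))
        reject[idx, : res.shape[1]] = res

    def _rate_se(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        p = float(x.mean())
        return p, math.sqrt(p * (1 - p) / x.size)

    rates, ses = {}, {}
    for j, k in enumerate(range(1, design.K + 1)):
        rates[k], ses[k] = _rate_se(reject[:, j])
    if add_mask.any():
        rates[design.new_arm], ses[design.new_arm] = _rate_se(
            reject[add_mask, design.K]
        )
    fwer, fwer_se = _rate_se(reject.any(axis=1))
    return OperatingCharacteristics(
        rejection_rate=rates,
        rejection_se=ses,
        fwer=fwer,
        fwer_se=fwer_se,
        decision_freq={ADD: float(add_mask.mean()), NO_ADD: float(1 - add_mask.mean())},
        n_sims=n,
    )
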