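"""Expected utilities, rejection-pattern probabilities, and the decision rule.

Two utilities capture different trial objectives:

* ``count`` — the number of rejected hypotheses; its expectation is the
  expected number of rejections, the sum of the marginal rejection
  probabilities.
* ``disjunctive`` — 1 if at least one hypothesis is rejected; its
  expectation is the disjunctive power, one minus the probability that every
  contrast stays below its threshold.

Given the stage-one data, the expected utility of each candidate plan is an
integral over the joint predictive of :mod:`addarm.testing`.  The optimal
interim decision maximises expected utility; differences smaller than an
indifference half-width ``epsilon`` (default 0.01) are reported as
``indifferent``, since at that scale numerical integration error and
non-statistical considerations dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._mvn import DEFAULT_SEED, DEFAULT_TOL, rectangle_probability
from .bayes import NormalPrior
from .designs import ADD, NO_ADD, Stage2Plan, TrialDesign, equal_split, make_plan
from .testing import JointPredictive, Stage1Observation, joint_predictive

__all__ = [
    "UTILITY_KINDS",
    "DecisionOutcome",
    "marginal_rejection_probs",
    "expected_count_utility",
    "disjunctive_utility",
    "expected_utility",
    "pattern_probability",
    "exact_count_distribution",
    "decide",
    "decision_map_priors",
    "decision_map_stage1",
]

UTILITY_KINDS = ("count", "disjunctive")
INDIFFERENT = "indifferent"


def _check_kind(kind: str) -> None:
    if kind not in UTILITY_KINDS:
        raise ValueError(f"utility kind must be one of {UTILITY_KINDS}, got {kind!r}")


@dataclass(frozen=True)
class DecisionOutcome:
    """Expected utility of each action and the resulting verdict.

    ``optimal`` is ``'add'``, ``'no_add'`` or ``'indifferent'``; the verdict
    is ``indifferent`` whenever ``|eu_add - eu_noadd| < epsilon`` (an open
    band, so exact ties also land here).
    """

    eu_add: float
    eu_noadd: float
    optimal: str
    epsilon: float

    @classmethod
    def from_utilities(
        cls, eu_add: float, eu_noadd: float, epsilon: float
    ) -> "DecisionOutcome":
        if epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if abs(eu_add - eu_noadd) < epsilon or eu_add == eu_noadd:
            optimal = INDIFFERENT
        elif eu_add > eu_noadd:
            optimal = ADD
        else:
            optimal = NO_ADD
        return cls(eu_add=eu_add, eu_noadd=eu_noadd, optimal=optimal, epsilon=epsilon)


def marginal_rejection_probs(jp: JointPredictive) -> np.ndarray:
    """Per-hypothesis predictive rejection probability P(Y_k > Z_k)."""
    sd = np.sqrt(np.diag(jp.cov))
    return norm.sf(jp.thresholds, loc=jp.mean, scale=sd)


def expected_count_utility(jp: JointPredictive) -> float:
    """Expected number of rejected hypotheses.

    By linearity this is the sum of the marginal rejection probabilities;
    the correlation structure is irrelevant for the mean count.
    """
    return float(marginal_rejection_probs(jp).sum())


def disjunctive_utility(
    jp: JointPredictive, *, tol: float = DEFAULT_TOL, seed: int = DEFAULT_SEED
) -> float:
    """Predictive probability of rejecting at least one hypothesis.

    One minus a single multivariate-normal rectangle probability (all
    contrasts below their thresholds); the shared-control correlation
    matters here, unlike for the expected count.
    """
    p_none = rectangle_probability(
        jp.mean, jp.cov, upper=jp.thresholds, tol=tol, seed=seed
    )
    return float(min(1.0, max(0.0, 1.0 - p_none)))


def expected_utility(
    jp: JointPredictive,
    kind: str,
    *,
    tol: float = DEFAULT_TOL,
    seed: int = DEFAULT_SEED,
) -> float:
    """Expected utility of the given kind under ``jp``."""
    _check_kind(kind)
    if kind == "count":
        return expected_count_utility(jp)
    return disjunctive_utility(jp, tol=tol, seed=seed)


def pattern_probability(
    jp: JointPredictive,
    reject_set: Iterable[int],
    *,
    tol: float = DEFAULT_TOL,
    seed: int = DEFAULT_SEED,
) -> float:
    """Probability of rejecting exactly the hypotheses in ``reject_set``.

    ``reject_set`` holds positions into ``jp.arm_order``.  The event is a
    rectangle: contrasts in the set exceed their thresholds, all others stay
    below.
    """
    reject = set(reject_set)
    if not reject <= set(range(jp.dim)):
        raise ValueError(
            f"reject_set must be a subset of hypothesis positions 0..{jp.dim - 1}"
        )
    lower = np.where(
        np.isin(np.arange(jp.dim), list(reject)), jp.thresholds, -np.inf
    )
    upper = np.where(np.isinf(lower), jp.thresholds, np.inf)
    return rectangle_probability(jp.mean, jp.cov, lower, upper, tol=tol, seed=seed)


def exact_count_distribution(
    jp: JointPredictive, *, tol: float = DEFAULT_TOL, seed: int = DEFAULT_SEED
) -> np.ndarray:
    """Distribution of the number of rejections, by 2^m subset enumeration.

    Entry ``v`` is the probability of rejecting exactly ``v`` hypotheses.
    Limited to m <= 12 hypotheses; the framework needs no more than a
    handful.
    """
    m = jp.dim
    if m > 12:
        raise ValueError(f"subset enumeration supports at most 12 hypotheses, got {m}")
    dist = np.zeros(m + 1)
    for v in range(m + 1):
        dist[v] = sum(
            pattern_probability(jp, subset, tol=tol, seed=seed)
            for subset in combinations(range(m), v)
        )
    return dist


def decide(
    design: TrialDesign,
    priors: Mapping[int, NormalPrior],
    obs: Stage1Observation,
    plan_add: Stage2Plan,
    plan_noadd: Stage2Plan,
    kind: str,
    epsilon: float = 0.01,
    *,
    tol: float = DEFAULT_TOL,
    seed: int = DEFAULT_SEED,
) -> DecisionOutcome:
    """Evaluate both candidate plans and pick the utility-maximising action."""
    _check_kind(kind)
    if plan_add.decision != ADD or plan_noadd.decision != NO_ADD:
        raise ValueError("plan_add must be an 'add' plan and plan_noadd a 'no_add' plan")
    jp_add = joint_predictive(design, plan_add, priors, obs)
    jp_noadd = joint_predictive(design, plan_noadd, priors, obs)
    eu_add = expected_utility(jp_add, kind, tol=tol, seed=seed)
    eu_noadd = expected_utility(jp_noadd, kind, tol=tol, seed=seed)
    return DecisionOutcome.from_utilities(eu_add, eu_noadd, epsilon)


def decision_map_priors(
    design: TrialDesign,
    obs: Stage1Observation,
    priors: Mapping[int, NormalPrior],
    grid_arm: int,
    means: Sequence[float],
    variances: Sequence[float],
    plan_add: Stage2Plan,
    plan_noadd: Stage2Plan,
    kind: str,
    epsilon: float = 0.01,
    *,
    tol: float = DEFAULT_TOL,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Optimal decision over a grid of prior moments for one arm.

    ``priors`` fixes every other arm; the prior of ``grid_arm`` sweeps the
    Cartesian product of ``means`` and ``variances``.  Returns one row per
    grid point with columns ``m0, v0, eu_add, eu_noadd, label``.
    """
    if len(means) == 0 or len(variances) == 0:
        raise ValueError("prior-moment grids must be nonempty")
    rows = []
    for m0 in means:
        for v0 in variances:
            pri = dict(priors)
            pri[grid_arm] = NormalPrior(mean=m0, variance=v0)
            out = decide(
                design, pri, obs, plan_add, plan_noadd, kind, epsilon,
                tol=tol, seed=seed,
            )
            rows.append((m0, v0, out.eu_add, out.eu_noadd, out.optimal))
    return pd.DataFrame(rows, columns=["m0", "v0", "eu_add", "eu_noadd", "label"])


def decision_map_stage1(
    design: TrialDesign,
    priors: Mapping[int, NormalPrior],
    grid_arms: tuple[int, int],
    x_values: Sequence[float],
    y_values: Sequence[float],
    plan_add: Stage2Plan | None = None,
    plan_noadd: Stage2Plan | None = None,
    fixed_means: Mapping[int, float] | None = None,
    kind: str = "count",
    epsilon: float = 0.01,
    *,
    tol: float = DEFAULT_TOL,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Optimal decision over a grid of stage-one sample means.

    ``grid_arms = (i, j)`` vary over ``x_values`` x ``y_values``; any
    remaining arms take their means from ``fixed_means``.  Plans default to
    an equal split of the stage-two total across the arms each decision
    carries.  Returns one row per grid point with columns
    ``xbar_i, xbar_j, eu_add, eu_noadd, label``.
    """
    if len(x_values) == 0 or len(y_values) == 0:
        raise ValueError("stage-one grids must be nonempty")
    ax, ay = grid_arms
    all_arms = set(range(design.K + 1))
    if not {ax, ay} <= all_arms:
        raise ValueError(f"grid arms must be stage-one arms 0..{design.K}")
    fixed = dict(fixed_means or {})
    missing = all_arms - {ax, ay} - set(fixed)
    if missing:
        raise ValueError(f"fixed_means must cover arms {sorted(missing)}")
    if plan_noadd is None:
        plan_noadd = make_plan(design, NO_ADD, equal_split(design.N2, design.K + 1))
    if plan_add is None:
        plan_add = make_plan(design, ADD, equal_split(design.N2, design.K + 2))
    rows = []
    for x in x_values:
        for y in y_values:
            means = dict(fixed)
            means[ax], means[ay] = x, y
            obs = Stage1Observation(xbar1=means)
            out = decide(
                design, priors, obs, plan_add, plan_noadd, kind, epsilon,
                tol=tol, seed=seed,
            )
            rows.append((x, y, out.eu_add, out.eu_noadd, out.optimal))
    return pd.DataFrame(
        rows, columns=[f"xbar_{ax}", f"xbar_{ay}", "eu_add", "eu_noadd", "label"]
    )
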