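"""Rejection thresholds and the joint predictive distribution of contrasts.

At the final analysis each initial arm ``k`` is tested with a weighted Wald
statistic combining both stages,

    [(w_k1*Xbar_k.1 + w_k2*Xbar_k.2) - (w_01*Xbar_0.1 + w_02*Xbar_0.2)]
        / sqrt(sigma_k^2/n_k + sigma_0^2/n_0)  >  b,

with stage weights ``w_ks = n_ks / n_k``.  Conditional on the stage-one
data, rejecting is the event that the stage-two weighted contrast

    Y_k = w_k2*Xbar_k.2 - w_02*Xbar_0.2

exceeds a fixed threshold Z_k that absorbs the boundary and the observed
stage-one contribution.  A newly added arm is compared against concurrent
(stage-two) control only: Y_{K+1} = Xbar_{K+1,2} - Xbar_0.2.

Under the predictive distributions of :mod:`addarm.bayes` the vector of
contrasts is multivariate normal; the shared stage-two control mean induces
positive correlation between hypotheses.  Every expected utility downstream
is an integral over rectangles of this distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .bayes import NormalPrior, posterior_update
from .designs import ADD, Stage2Plan, TrialDesign

__all__ = [
    "Stage1Observation",
    "JointPredictive",
    "stage2_threshold",
    "newarm_threshold",
    "joint_predictive",
]


@dataclass(frozen=True)
class Stage1Observation:
    """Observed stage-one sample means for arms ``0..K``."""

    xbar1: Mapping[int, float]

    def arms(self) -> set[int]:
        return set(self.xbar1)


@dataclass(frozen=True)
class JointPredictive:
    """Joint normal law of the stage-two contrasts, with thresholds.

    ``arm_order[i]`` names the hypothesis arm behind coordinate ``i`` of
    ``mean``, ``cov`` and ``thresholds``.  Hypothesis ``i`` is rejected when
    the contrast exceeds ``thresholds[i]``.
    """

    arm_order: tuple[int, ...]
    mean: np.ndarray
    cov: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        thr = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        object.__setattr__(self, "arm_order", tuple(self.arm_order))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "thresholds", thr)
        m = len(self.arm_order)
        if mean.shape != (m,) or thr.shape != (m,) or cov.shape != (m, m):
            raise ValueError("inconsistent dimensions in JointPredictive")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(cov) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def dim(self) -> int:
        return len(self.arm_order)


def stage2_threshold(
    b: float,
    sigma2_k: float,
    sigma2_0: float,
    n_k: int,
    n_0: int,
    w_k1: float,
    w_01: float,
    xbar_k1: float,
    xbar_01: float,
) -> float:
    """Stage-two rejection threshold for an initial arm.

    Z = b * sqrt(sigma_k^2/n_k + sigma_0^2/n_0) - (w_k1*xbar_k1 - w_01*xbar_01):
    the final boundary on the contrast scale minus the evidence already
    banked in stage one.  Decreasing in ``xbar_k1``, increasing in
    ``xbar_01``.
    """
    if sigma2_k <= 0 or sigma2_0 <= 0:
        raise ValueError("variances must be positive")
    if n_k < 1 or n_0 < 1:
        raise ValueError("total sample sizes must be positive")
    se = math.sqrt(sigma2_k / n_k + sigma2_0 / n_0)
    return b * se - (w_k1 * xbar_k1 - w_01 * xbar_01)


def newarm_threshold(
    b: float, sigma2_new: float, n_new2: int, sigma2_0: float, n02: int
) -> float:
    """Rejection threshold for the newly added arm.

    The new arm has no stage-one data and is compared against concurrent
    control, so Z = b * sqrt(sigma_{K+1}^2/n_{K+1,2} + sigma_0^2/n02).
    """
    if sigma2_new <= 0 or sigma2_0 <= 0:
        raise ValueError("variances must be positive")
    if n_new2 < 1 or n02 < 1:
        raise ValueError("stage-two sample sizes must be positive")
    return b * math.sqrt(sigma2_new / n_new2 + sigma2_0 / n02)


def joint_predictive(
    design: TrialDesign,
    plan: Stage2Plan,
    priors: Mapping[int, NormalPrior],
    obs: Stage1Observation,
) -> JointPredictive:
    """Assemble the joint predictive of all stage-two contrasts.

    For an initial arm ``k`` the contrast Y_k = w_k2*Xbar_k.2 - w_02*Xbar_0.2
    has predictive mean ``w_k2 * m_k1`` and variance
    ``w_k2^2 (sigma_k^2/n_k2 + v_k1) + w_02^2 sigma_0^2/n02``.  Under an
    ``add`` plan the new arm contributes Y_{K+1} = Xbar_{K+1,2} - Xbar_0.2
    with mean ``m_{K+1,0}`` and variance
    ``sigma_{K+1}^2/n_{K+1,2} + v_{K+1,0} + sigma_0^2/n02``.  The shared
    stage-two control mean gives covariance ``w_02^2 sigma_0^2/n02`` between
    initial-arm pairs and ``w_02 sigma_0^2/n02`` between an initial arm and
    the new one.
    """
    if obs.arms() != set(range(design.K + 1)):
        raise ValueError(
            f"stage-one observations must cover arms 0..{design.K}, "
            f"got {sorted(obs.arms())}"
        )
    hyp_arms = list(range(1, design.K + 1))
    adding = plan.decision == ADD
    if adding:
        hyp_arms.append(design.new_arm)
    if set(plan.n2) != set(range(design.K + 1)) | set(hyp_arms):
        raise ValueError("plan allocations do not match the design's arms")
    missing = [k for k in hyp_arms if k not in priors]
    if missing:
        raise ValueError(f"missing priors for arms {missing}")

    n01 = design.n1[0]
    n02 = plan.n2[0]
    n0 = n01 + n02
    w01, w02 = n01 / n0, n02 / n0
    sig0 = design.sigma2[0]
    control_var = sig0 / n02

    m = len(hyp_arms)
    mean = np.empty(m)
    var = np.empty(m)
    thr = np.empty(m)
    w2 = np.empty(m)  # multiplier of the shared control mean per contrast
    for i, k in enumerate(hyp_arms):
        sigk = design.sigma2[k]
        nk2 = plan.n2[k]
        if k == design.new_arm:
            prior = priors[k]
            mean[i] = prior.mean
            var[i] = sigk / nk2 + prior.variance + control_var
            thr[i] = newarm_threshold(plan.boundary, sigk, nk2, sig0, n02)
            w2[i] = 1.0
        else:
            nk1 = design.n1[k]
            nk = nk1 + nk2
            wk1, wk2 = nk1 / nk, nk2 / nk
            post = posterior_update(priors[k], obs.xbar1[k], sigk, nk1)
            mean[i] = wk2 * post.mean
            var[i] = wk2**2 * (sigk / nk2 + post.variance) + w02**2 * control_var
            thr[i] = stage2_threshold(
                plan.boundary, sigk, sig0, nk, n0, wk1, w01, obs.xbar1[k], obs.xbar1[0]
            )
            w2[i] = w02

    # shared-control covariance: (coef_j * coef_k) * sigma0^2/n02
    cov = np.outer(w2, w2) * control_var
    np.fill_diagonal(cov, var)
    return JointPredictive(
        arm_order=tuple(hyp_arms), mean=mean, cov=cov, thresholds=thr
    )
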