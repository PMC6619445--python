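"""Conjugate normal updates and stage-two predictive distributions.

Each experimental arm ``k`` has an unknown mean effect ``mu_k`` with a normal
prior N(m_k0, v_k0) and known sampling variance ``sigma_k^2``.  After stage
one the prior is updated in closed form; the stage-two sample mean then has a
normal predictive distribution whose variance is the sampling variance of the
stage-two mean plus the (posterior) uncertainty about ``mu_k``.  The control
mean is fixed at zero and never updated — stage-one control data enter the
framework only through the rejection thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "NormalPrior",
    "PosteriorState",
    "PredictiveNormal",
    "posterior_update",
    "predictive_stage2",
    "control_predictive",
]


@dataclass(frozen=True)
class NormalPrior:
    """Prior moments (m0, v0) for an arm's mean effect."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class PosteriorState:
    """Posterior moments (m1, v1) after observing stage one."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("posterior variance must be positive")


@dataclass(frozen=True)
class PredictiveNormal:
    """Normal predictive distribution of a future stage sample mean."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("predictive variance must be positive")


def posterior_update(
    prior: NormalPrior, xbar1: float, sigma2: float, n1: int
) -> PosteriorState:
    """Update a normal prior with a stage-one sample mean.

    With sampling variance ``sigma2 / n1`` for the observed mean, the
    posterior mean is the precision-weighted average of prior mean and data,

        m1 = (v0 * xbar1 + (sigma2/n1) * m0) / (sigma2/n1 + v0),

    and the posterior precision is the sum of precisions,

        1/v1 = 1/v0 + n1/sigma2.
    """
    if sigma2 <= 0:
        raise ValueError("sampling variance must be positive")
    if n1 < 1:
        raise ValueError("stage-one sample size must be >= 1")
    s = sigma2 / n1
    m1 = (prior.variance * xbar1 + s * prior.mean) / (s + prior.variance)
    v1 = 1.0 / (1.0 / prior.variance + n1 / sigma2)
    return PosteriorState(mean=m1, variance=v1)


def predictive_stage2(
    state: Union[PosteriorState, NormalPrior], sigma2: float, n2: int
) -> PredictiveNormal:
    """Predictive distribution of an arm's stage-two sample mean.

    ``state`` carries the current moments of the arm's mean effect: the
    posterior for an initial arm, the untouched prior for a newly added arm.
    The predictive is N(state.mean, sigma2/n2 + state.variance).
    """
    if sigma2 <= 0:
        raise ValueError("sampling variance must be positive")
    if n2 < 1:
        raise ValueError("no predictive distribution exists for an unsampled arm")
    return PredictiveNormal(mean=state.mean, variance=sigma2 / n2 + state.variance)


def control_predictive(sigma2_0: float, n02: int) -> PredictiveNormal:
    """Stage-two predictive of the control mean: N(0, sigma0^2 / n02).

    The control effect is a known zero, so the only uncertainty is sampling
    noise in the stage-two control mean.
    """
    if sigma2_0 <= 0:
        raise ValueError("control variance must be positive")
    if n02 < 1:
        raise ValueError("control must be sampled in stage two")
    return PredictiveNormal(mean=0.0, variance=sigma2_0 / n02)
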