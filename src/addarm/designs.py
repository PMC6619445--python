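"""Trial context and candidate stage-two plans.

A two-stage multiarm trial starts with ``K`` experimental arms plus a shared
control (arm 0).  At the interim, the sponsor chooses between two stage-two
plans: continue as designed (``no_add``) or open a new experimental arm
``K + 1`` (``add``).  Adding an arm splits the fixed stage-two sample across
more arms and tightens the per-hypothesis rejection boundary through a
Bonferroni correction, so the choice is a genuine trade-off.

Outcomes are normal with known per-arm variances; every hypothesis is a
one-sided comparison of an experimental arm against control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from scipy.stats import norm

__all__ = [
    "TrialDesign",
    "Stage2Plan",
    "equal_split",
    "bonferroni_boundary",
    "make_plan",
]

ADD = "add"
NO_ADD = "no_add"


@dataclass(frozen=True)
class TrialDesign:
    """Fixed context of the trial.

    Parameters
    ----------
    K
        Number of initial experimental arms (arm indices ``1..K``;
        arm 0 is control, arm ``K + 1`` the candidate new arm).
    n1
        Stage-one sample size per arm, for arms ``0..K``.
    sigma2
        Known outcome variance per arm, for arms ``0..K+1`` (the candidate
        arm needs a variance even though it has no stage-one data).
    alpha
        One-sided significance / family-wise error level, in (0, 0.5).
    N2
        Total stage-two sample size shared by whichever plan is chosen.
    """

    K: int
    n1: Mapping[int, int]
    sigma2: Mapping[int, float]
    alpha: float
    N2: int

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"need at least one initial arm, got K={self.K}")
        if set(self.n1) != set(range(self.K + 1)):
            raise ValueError(
                f"n1 must cover arms 0..{self.K}, got {sorted(self.n1)}"
            )
        if set(self.sigma2) != set(range(self.K + 2)):
            raise ValueError(
                f"sigma2 must cover arms 0..{self.K + 1}, got {sorted(self.sigma2)}"
            )
        for k, n in self.n1.items():
            if int(n) != n or n < 1:
                raise ValueError(f"stage-one sample size of arm {k} must be >= 1")
        for k, s in self.sigma2.items():
            if s <= 0:
                raise ValueError(f"variance of arm {k} must be positive")
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if int(self.N2) != self.N2 or self.N2 < 1:
            raise ValueError("N2 must be a positive integer")

    @property
    def N1(self) -> int:
        """Total stage-one sample size."""
        return sum(self.n1.values())

    @property
    def new_arm(self) -> int:
        """Index of the candidate new arm."""
        return self.K + 1


@dataclass(frozen=True)
class Stage2Plan:
    """A candidate stage-two layout: arm allocations and rejection boundary.

    ``num_hypotheses`` is ``K`` for ``no_add`` and ``K + 1`` for ``add``;
    ``boundary`` is the Bonferroni-adjusted standard-normal quantile applied
    to every final test statistic.
    """

    decision: str
    n2: Mapping[int, int]
    num_hypotheses: int
    boundary: float
    total: int = field(default=0)

    def __post_init__(self) -> None:
        if self.decision not in (ADD, NO_ADD):
            raise ValueError(f"decision must be '{ADD}' or '{NO_ADD}'")
        alloc = sum(self.n2.values())
        total = self.total if self.total else alloc
        object.__setattr__(self, "total", total)
        if alloc != total:
            raise ValueError(
                f"allocations sum to {alloc}, declared stage-two total is {total}"
            )
        for k, n in self.n2.items():
            if int(n) != n or n < 1:
                raise ValueError(f"stage-two sample size of arm {k} must be >= 1")


def equal_split(total: int, num_arms: int) -> dict[int, int]:
    """Split ``total`` patients as evenly as possible across ``num_arms`` arms.

    Sizes differ by at most one; remainder units go to the highest arm
    indices, i.e. the newest arms.  ``equal_split(100, 3)`` gives
    ``{0: 33, 1: 33, 2: 34}``.
    """
    if num_arms < 1:
        raise ValueError("need at least one arm")
    if total < 1:
        raise ValueError("total must be positive")
    base, rem = divmod(total, num_arms)
    return {k: base + (1 if k >= num_arms - rem else 0) for k in range(num_arms)}


def bonferroni_boundary(alpha: float, num_hypotheses: int) -> float:
    """Standard-normal upper quantile at ``alpha / num_hypotheses``.

    This is the per-hypothesis critical value that controls the family-wise
    error rate at ``alpha`` in the strong sense via Bonferroni.  With a single
    hypothesis no correction is applied.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if num_hypotheses < 1:
        raise ValueError("need at least one hypothesis")
    return float(norm.isf(alpha / num_hypotheses))


def make_plan(
    design: TrialDesign,
    decision: str,
    n2: Mapping[int, int],
    total: int | None = None,
) -> Stage2Plan:
    """Build a validated :class:`Stage2Plan` for ``design``.

    ``n2`` must cover exactly arms ``0..K`` for ``no_add`` and ``0..K+1``
    for ``add``.  ``total`` defaults to ``design.N2``; passing a larger value
    with ``decision='add'`` expresses the variant where extra patients are
    recruited for the new arm.
    """
    if decision == NO_ADD:
        expected = set(range(design.K + 1))
    elif decision == ADD:
        expected = set(range(design.K + 2))
    else:
        raise ValueError(f"decision must be '{ADD}' or '{NO_ADD}', got {decision!r}")
    if set(n2) != expected:
        raise ValueError(
            f"decision {decision!r} needs allocations for arms "
            f"{sorted(expected)}, got {sorted(n2)}"
        )
    if total is None:
        total = design.N2
    num_hyp = design.K + (1 if decision == ADD else 0)
    return Stage2Plan(
        decision=decision,
        n2=dict(n2),
        num_hypotheses=num_hyp,
        boundary=bonferroni_boundary(design.alpha, num_hyp),
        total=total,
    )
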