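"""Ready-made trial configurations used throughout the docs and tests.

``case_study`` reconstructs the knee-osteoarthritis cryoneurolysis trial
(treatment vs sham control, WOMAC pain change at day 30, 2:1 randomisation,
final totals 121/59) as a hypothetical two-stage design with one interim at
80 patients and the option to add a second experimental arm.  The two
illustration fixtures are fully synthetic pre-trial settings for mapping how
the optimal decision depends on the stage-one sample means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .bayes import NormalPrior
from .designs import ADD, NO_ADD, Stage2Plan, TrialDesign, equal_split, make_plan
from .testing import Stage1Observation

__all__ = [
    "Fixture",
    "case_study",
    "illustration_one_initial_arm",
    "illustration_two_initial_arms",
]


@dataclass(frozen=True)
class Fixture:
    """A complete decision problem: design, priors, stage-one data, plans."""

    design: TrialDesign
    priors: Mapping[int, NormalPrior]
    obs: Stage1Observation | None
    plan_add: Stage2Plan
    plan_noadd: Stage2Plan


def case_study() -> Fixture:
    """Knee-osteoarthritis case study.

    Final per-arm totals 121 (treatment) and 59 (control) with reported
    standard errors 1.26 and 1.63 give known variances sigma1^2 =
    1.26^2*121 and sigma0^2 = 1.63^2*59 (treated as exact).  At the interim
    (80 enrolled: 53 treatment, 27 control) the observed means are 8 and 5.
    Not adding keeps the original allocation {32, 68}; adding splits the
    remaining 100 patients {33, 33, 34} with the extra unit on the new arm
    and a Bonferroni boundary over two hypotheses.  Priors: (0, 10) for the
    initial treatment, (5, 10) for the candidate arm, which shares the
    treatment's variance.
    """
    sigma1 = 1.26**2 * 121
    sigma0 = 1.63**2 * 59
    design = TrialDesign(
        K=1,
        n1={0: 27, 1: 53},
        sigma2={0: sigma0, 1: sigma1, 2: sigma1},
        alpha=0.025,
        N2=100,
    )
    priors = {1: NormalPrior(0.0, 10.0), 2: NormalPrior(5.0, 10.0)}
    obs = Stage1Observation(xbar1={0: 5.0, 1: 8.0})
    plan_noadd = make_plan(design, NO_ADD, {0: 32, 1: 68})
    plan_add = make_plan(design, ADD, {0: 33, 1: 33, 2: 34})
    return Fixture(design, priors, obs, plan_add, plan_noadd)


def illustration_one_initial_arm() -> Fixture:
    """Pre-trial setting: one treatment plus control, N1=400, N2=300.

    Equal stage-one allocation (200 per arm), family-wise level 5%.  Not
    adding gives 150 per arm in stage two; adding gives 100 per arm across
    three arms with a two-hypothesis Bonferroni boundary.  Outcome variances
    are 1 and priors standard normal — the neutral defaults for a
    standardised effect scale.  No stage-one data are fixed: supply them per
    grid point.
    """
    design = TrialDesign(
        K=1,
        n1={0: 200, 1: 200},
        sigma2={0: 1.0, 1: 1.0, 2: 1.0},
        alpha=0.05,
        N2=300,
    )
    priors = {1: NormalPrior(0.0, 1.0), 2: NormalPrior(0.0, 1.0)}
    plan_noadd = make_plan(design, NO_ADD, equal_split(300, 2))
    plan_add = make_plan(design, ADD, equal_split(300, 3))
    return Fixture(design, priors, None, plan_add, plan_noadd)


def illustration_two_initial_arms() -> Fixture:
    """Pre-trial setting: two treatments plus control, N1=1200, N2=1800.

    400 per arm in stage one, family-wise level 5%.  Not adding gives 600
    per arm across three arms; adding gives 450 per arm across four, with
    Bonferroni over three hypotheses.  Variances 1, standard-normal priors.
    """
    design = TrialDesign(
        K=2,
        n1={0: 400, 1: 400, 2: 400},
        sigma2={0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0},
        alpha=0.05,
        N2=1800,
    )
    priors = {k: NormalPrior(0.0, 1.0) for k in (1, 2, 3)}
    plan_noadd = make_plan(design, NO_ADD, equal_split(1800, 3))
    plan_add = make_plan(design, ADD, equal_split(1800, 4))
    return Fixture(design, priors, None, plan_add, plan_noadd)
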