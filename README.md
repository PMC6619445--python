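# addarm — should a platform trial open a new treatment arm at interim?

`addarm` implements a decision-theoretic framework for a two-stage multiarm
trial that must decide, after seeing stage-one data, whether to add a new
experimental arm. It is aimed at trial statisticians designing platform or
multiarm-multistage studies with normally distributed outcomes and a shared
control arm.

## The problem and the model

A trial starts with `K` experimental arms and a control (arm 0), observes
stage-one sample means `x̄_k.1`, and has `N₂` patients left. Opening a new
arm `K+1` buys a chance at an extra rejection, but dilutes the stage-two
allocations and tightens the per-hypothesis boundary from `Φ⁻¹(1−α)` to the
Bonferroni value `Φ⁻¹(1−α/(K+1))`.

Outcomes are normal with known variances `σ_k²`; each effect `μ_k` has a
normal prior N(m_k0, v_k0) (control is fixed at `μ₀ = 0`). After stage one
the prior updates in closed form to N(m_k1, v_k1). Arm `k` is finally tested
with the weighted Wald statistic

    [(w_k1 x̄_k.1 + w_k2 X̄_k.2) − (w_01 x̄_0.1 + w_02 X̄_0.2)]
        / √(σ_k²/n_k + σ₀²/n₀)  >  b,        w_ks = n_ks / n_k,

which, conditional on stage one, is the event that the stage-two contrast
`Y_k = w_k2 X̄_k.2 − w_02 X̄_0.2` exceeds a fixed threshold `Z_k`. A newly
added arm is compared against concurrent control only:
`Y_{K+1} = X̄_{K+1,2} − X̄_0.2`. Under the predictive distributions the
contrast vector is multivariate normal with shared-control correlations, so
the expected utility of either action is a normal rectangle probability:

* **count** utility `U^c` — the number of rejected hypotheses; `E[U^c]` is
  the sum of the marginal rejection probabilities;
* **disjunctive** utility `U^o` — 1 if at least one hypothesis is rejected;
  `E[U^o] = 1 − P(all Y_k ≤ Z_k)`, the disjunctive power.

The optimal action maximises the chosen expected utility; differences
smaller than an indifference band ε (0.01 by default) are reported as
`indifferent`.

## Worked example

The shipped fixture reconstructs a knee-osteoarthritis trial (treatment vs
sham, 2:1 randomisation, final totals 121/59, known variances from the
reported standard errors 1.26 and 1.63) as a hypothetical two-stage design:
at the interim 53 + 27 patients show means 8 and 5, and 100 patients remain.
Not adding keeps the `{32, 68}` split; adding splits `{33, 33, 34}` across
control, the initial arm and a new arm with prior N(5, 10).

```python
from addarm import case_study, decide

fx = case_study()
for kind in ("count", "disjunctive"):
    out = decide(fx.design, fx.priors, fx.obs, fx.plan_add, fx.plan_noadd,
                 kind, epsilon=0.0)
    print(kind, round(out.eu_add, 3), round(out.eu_noadd, 3), out.optimal)
```

prints

```
count 0.811 0.606 add
disjunctive 0.605 0.606 no_add
```

Read: adding the arm raises the expected number of rejections from 0.606 to
0.811 (the new hypothesis can only add rejections), so `add` is optimal for
a trial that counts successes. Disjunctive power, in contrast, drops
slightly (0.606 → 0.605): the thinner allocation and stricter boundary cost
about as much as the new arm contributes, so a trial that only needs one
rejection should not add — though a margin of 0.001 is well inside any
practical indifference band.

The `examples/` directory has one short script per capability: the decision
above, decision maps over prior moments and over stage-one means, a Monte
Carlo cross-check of the analytic utilities, and frequentist operating
characteristics of add-arm policies. A YAML configuration
(`examples/case_study.yaml`) drives the same analyses from the shell:

```sh
addarm decide -c examples/case_study.yaml
addarm map priors -c examples/case_study.yaml --out map.tsv
addarm oc -c examples/case_study.yaml
```

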