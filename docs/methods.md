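# Methods

## Model and procedure

`addarm` evaluates one interim decision in a two-stage multiarm trial:
continue with the `K` initial experimental arms (`no_add`) or open arm
`K+1` (`add`). Individual outcomes on arm `k` are i.i.d. N(μ_k, σ_k²) with
σ_k² known; the control effect is fixed, μ₀ = 0, and each experimental
effect carries a normal prior N(m_k0, v_k0). The framework is Bayesian
before the data — expected utilities are predictive probabilities given the
stage-one means — but the utilities themselves are frequentist test
outcomes: one-sided Wald rejections at family-wise level α, Bonferroni
corrected when more than one hypothesis is tested.

The pipeline for either candidate plan is:

1. conjugate update of each initial arm's prior with its stage-one mean
   (`bayes.posterior_update`);
2. thresholds on the stage-two contrast scale: for an initial arm,
   `Z_k = b·√(σ_k²/n_k + σ₀²/n₀) − (w_k1 x̄_k.1 − w_01 x̄_0.1)`; for a new
   arm, `Z_{K+1} = b·√(σ_{K+1}²/n_{K+1,2} + σ₀²/n₀₂)` (`testing`);
3. the joint normal law of the contrasts `Y_k` with shared-control
   covariances `w₀₂²σ₀²/n₀₂` (initial–initial) and `w₀₂σ₀²/n₀₂`
   (initial–new) (`testing.joint_predictive`);
4. expected utilities as rectangle probabilities of that law, and the
   argmax decision with an optional indifference band (`utilities`).

## The weighting convention

Two formulations of the final test circulate for this design: one states
the rejection event on the *unweighted* stage-two difference
`X̄_k.2 − X̄_0.2` while keeping stage weights inside the threshold, the
other keeps the event on the weighted contrast `w_k2 X̄_k.2 − w_02 X̄_0.2`.
They are not equivalent, and mixing them double-counts or drops the weight
factors. This package uses the internally consistent weighted-contrast
convention throughout: the rejection event, its predictive mean
`w_k2 m_k1`, and its variance `w_k2²(σ_k²/n_k2 + v_k1) + w_02²σ₀²/n₀₂` all
carry the same weights, which is exactly the event the weighted Wald
statistic defines. On the case-study fixture this reproduces the reference
add-decision utilities to within input rounding (0.811 vs 0.815 expected
rejections; 0.605 vs 0.618 disjunctive power) while the no-add utility
evaluates to 0.606 against a reference 0.63 computed under the other
convention; the discrepancy is documented rather than patched.

A consequence worth noting: under this convention the case-study
disjunctive utilities differ by only 0.001, so with the default ε = 0.01
band the verdict is `indifferent`. The decision rule proper is the argmax
(ε = 0), which prefers `no_add`; ε is a reporting device for maps, not part
of the rule.

## Parameters that matter

| parameter | meaning | default / convention |
|---|---|---|
| `alpha` | one-sided family-wise error level | no default; 0.025 in the case study, 0.05 in the illustrations |
| `epsilon` | indifference half-width on expected utility (utility units) | 0.01; the band is open, `|Δ| < ε`, and exact ties are folded into `indifferent` |
| `N2`, `n2` | stage-two total and per-arm allocations (patients) | allocations are data, not derived: the case-study `{32, 68}` split back-solves from the real trial's totals and is not an equal split. `equal_split` assigns remainder units to the newest arms (`{33, 33, 34}`) |
| `mvn tol`, `mvn seed` | absolute tolerance and seed of the rectangle-probability integrator | 1e-6 and a fixed package seed; both exposed so results are bit-reproducible per configuration |

## Synthetic data and what passing tests show

The illustration fixtures and `simulate.simulate_stage1` generate the only
"data" in the package. Stage-one means are drawn exactly from the model:
N(μ_k, σ_k²/n_k1) with μ_k from its prior (prior-predictive mode) or fixed
(frequentist mode). The illustration settings use unit outcome variances
and standard-normal priors on a standardised effect scale, since the
pre-trial scenarios specify sample sizes and levels but not variances or
prior moments. Real trials differ in ways the generator does not emulate —
unknown and unequal variances, non-normal or delayed outcomes, missingness,
drift between stages — so green tests certify the probability calculus and
the decision logic under the stated model, not robustness to those
violations.

`simulate.frequentist_oc` is the honest check on the frequentist side
effects of the adaptive rule: stage-one and stage-two data are drawn at
fixed true means (priors enter only through the decision rule), the realised
plan's tests are applied, and empirical rejection rates are returned with
binomial standard errors. With the `never_add` policy this reduces to the
classical fixed design and recovers the nominal level; policies that can
change per-arm totals mid-trial may inflate the type-I error, and the
simulation quantifies that inflation — no analytic target exists for it.

## Numerical choices

* Rectangle probabilities use scipy's Genz quasi-Monte-Carlo integrator
  with absolute tolerance 1e-6 and a fixed seed; dimension 1 short-circuits
  to the closed-form normal CDF. Results are clipped to [0, 1].
* `exact_count_distribution` enumerates all 2^m rejection patterns and is
  capped at m = 12 hypotheses; the framework needs at most 3 or 4.
* Monte Carlo utilities draw contrast vectors via an SVD factorisation of
  the covariance, so positive semi-definite (including near-degenerate)
  covariances are accepted.
* `frequentist_oc` spawns separate child streams for stage one and stage
  two from the root seed, so different policies see identical stage-one
  data at the same seed. The vectorised `always_add`/`never_add` paths run
  10⁵ replicates in well under a second; `decision_rule` evaluates the full
  decision per replicate and is meant for 10²–10⁴ replicates.
* Degenerate inputs fail loudly: unsampled arms have no predictive
  distribution, non-positive variances and empty grids are rejected, and a
  plan must cover exactly the arms its decision implies.

## Test problem sizes

The default suite runs in a few seconds: Monte Carlo cross-checks at
2–5 × 10⁴ draws, operating characteristics at 2 × 10⁴ replicates. The
end-to-end acceptance tests use 10⁵ draws/replicates and a battery of 22
randomised configurations (44 joint predictives), chosen so the whole suite
stays comfortably interactive while keeping three-standard-error
comparisons meaningful.

## Known limitations

* Binary or otherwise non-normal outcomes, unknown variances and
  response-adaptive randomisation are out of scope; with large samples the
  normal approximation may stand in.
* The framework does not repair the type-I inflation an adaptive sample-size
  change can cause (combination tests or group-sequential adjustments
  would); it only measures it.
* Utilities are purely statistical — no monetary costs, trial duration or
  patient-benefit terms, though the decision rule accepts any utility that
  can be written as an expectation over the joint predictive.
* Estimation after adaptation (bias of the final effect estimates) is not
  addressed.
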