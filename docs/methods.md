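# Methods

## The three threshold models

A decision-maker facing a patient with disease probability `p` treats when
`p ≥ T` and withholds otherwise; the boundary `p = T` counts as
treatment-indicated throughout (decision rule and agreement rule use the
same convention, so an observed decision always agrees with the decision
the model itself would take).

**Expected-utility threshold.** `T_EUT = 1/(1 + B₂/H₂)`, where B₂ and H₂
are the objective benefit and harm magnitudes of the treatment taken from
the literature. This is the probability at which expected benefit `p·B₂`
equals expected harm `(1 − p)·H₂`; the package property-tests that the
threshold rule and the direct expected-value comparison give identical
decisions.

**Regret threshold.** `T_RG = 1/(1 + B₁/H₁)`, where `B₁/H₁` is the ratio
of anticipated regret of omission to regret of commission, elicited on a
dual visual analog scale (two 0–100 sliders). The mapping from marks to the
ratio is linear: `B₁/H₁ = omission mark / commission mark`. Published
DVAS instruments rarely document a transformation, so this linear-ratio
reading is a stated assumption of the package, not an established fact; it is scale-invariant
(only the ratio of marks matters) and spans the 0–100 ratio range observed
in practice. Responses with both marks at zero admit no ratio and are
excluded with a logged count rather than imputed. The randomized slider
anchor (start at 0 vs 100) is carried as metadata; no anchoring correction
is applied.

**Dual-processing threshold.** Type-1 (fast, affective) and type-2 (slow,
analytic) processing are mixed by `γ ∈ [0, 1]`, operationalized as the
relative distance between the two thresholds,
`γ = (T_EUT − T_RG)/T_EUT`, clamped into [0, 1]. The clamp at 1 is part of
the model's definition; the clamp at 0 (when the regret threshold exceeds
the expected-utility threshold) is this package's documented completion of
an otherwise silent case. The threshold itself is

```
T_DP = T_EUT · [1 + (γ/2)(1 − γ)(H₁/H₂)(1 − B₁/H₁)]        (default)
T_DP = T_EUT · [1 + γ/(2(1 − γ)) · (H₁/H₂)(1 − B₁/H₁)]     (variant "ratio")
```

The printed rendering of this formula is typographically ambiguous, so both
readings are implemented and neither is asserted as the original intent:
the default "product" parse is preferred because it is finite on all of
γ ∈ [0, 1] and reduces to `T_EUT` at both endpoints; the "ratio" parse
diverges as γ → 1 and its multiplier is capped at 10⁶ (the cap is
inconsequential after the final clamp). Both variants return exactly
`T_EUT` at γ = 0 and clamp the result into [0, 1], since extreme elicited
ratios can push the raw value outside the probability scale. Whether γ = 1
ought to force `T_DP` toward `T_RG` cannot be derived from the formula and
is deliberately not imposed.

Degenerate inputs: a zero harm with positive benefit means an infinite
benefit/harm ratio and threshold 0 (returned with a warning); benefit and
harm both zero is an undefined-input error; `T_EUT = 0` makes γ undefined.

## Study design

Six vignettes in a 2 × 3 within-subject factorial: condition (pulmonary
embolism, PE, familiar to most physicians; acute myeloid leukemia relapse,
AML, requiring specialist knowledge) × benefit–harm level (base,
low-threshold, high-threshold). Condition order, high/low case order and
the DVAS anchor are independently randomized per participant; every
participant answers all six vignettes.

No canonical objective benefit/harm magnitudes exist for these vignettes,
so the defaults are configuration values chosen to satisfy
the design's qualitative constraints, on the same 0–100 severity scale as
the DVAS marks so that H₁/H₂ is dimensionless and of order one:

| condition | level | B₂ | H₂ | B₂/H₂ | T_EUT | p(disease) |
|---|---|---|---|---|---|---|
| PE | base | 45 | 5 | 9 | 0.100 | 0.50 (explicit) |
| PE | low-threshold | 80 | 4 | 20 | 0.048 | 0.50 (explicit) |
| PE | high-threshold | 20 | 25 | 0.8 | 0.556 | 0.50 (explicit) |
| AML | base | 50 | 25 | 2 | 0.333 | 0.70 (latent) |
| AML | low-threshold | 80 | 20 | 4 | 0.200 | 0.90 (latent) |
| AML | high-threshold | 15 | 30 | 0.5 | 0.667 | 0.50 (latent) |

Two of these choices deserve comment. First, the high-threshold PE ratio is
set just *below* 1 (0.8) rather than at 1: with a ratio of exactly 1 the
normative threshold equals the stated 50% disease probability, and under
the boundary-inclusive decision rule an expected-utility-compliant
physician would still treat — the high-threshold manipulation could never
reverse the prescription, contradicting the design's purpose of producing a
case where most physicians withhold. Second, AML relapse probabilities are
never told to the respondent (experts are expected to infer "high" or "low"
risk); they exist here only as latent simulation parameters, with the high
relapse probability (0.9) attached to the low-threshold vignette where
treatment is most clearly indicated.

The per-condition normative thresholds are ordered
high-threshold > base > low-threshold, which the vignette configuration
validates as an invariant.

## The synthetic cohort

The simulator emulates the data-generating process of a vignette survey of
this design, so the whole pipeline is testable without access to any real
cohort. Each
simulated participant:

1. receives a randomization plan (orders, anchor);
2. produces an automatic pre-context benefit/harm pair per condition
   (log-normal ratio with medians 3.0 for PE and 2.0 for AML, σ = 0.5,
   around a uniform harm magnitude);
3. produces DVAS marks per vignette by drawing the omission share
   `u = omission/(omission + commission)` from a Beta distribution with
   concentration 5 whose mean is set by the vignette's target median regret
   ratio (PE: 3.18 / 5.26 / 0.98; AML: 1.00 / 1.94 / 0.50 for base /
   low-threshold / high-threshold — the only distributional anchors
   available), scaled by a uniform total mark intensity on [40, 100];
4. decides per vignette by their latent model's threshold (expected-utility,
   regret, or dual-processing with γ derived by the distance formula from
   their own marks; an optional latent γ distribution can override the
   distance-derived γ), flipping the implied decision with probability
   `decision_noise` (default 0.05, the value used in the recovery suite).

Within a condition the three vignettes share a participant's Beta quantile
(comonotone coupling), with the participant's overall quantile correlated
across conditions (ρ = 0.3). This encodes a consistent "regret style" per
respondent; it is what makes the low/base/high treatment gradient hold
deterministically in noise-free cohorts (the shared quantile plus the
stochastic ordering of the per-vignette Beta distributions gives each
participant ordered regret thresholds) and induces the within-subject
correlation the mixed model is there to absorb.

What the simulator does *not* emulate: order and anchoring effects on the
marks (randomization is generated but has no causal effect), response
times, learning across vignettes, and real physicians' heterogeneity in
interpreting qualitative risk language. Passing recovery tests therefore
show that the analysis identifies the generating model *under the model
family's own assumptions*, not that real cohorts are this well-behaved.

Measured under the default conditions (100 participants, 5% decision
noise, 50 seeded replicates per generating model), the analysis ranks the
generating model's agreement highest in 50/50 replicates for each of the
three models, and for dual-generated cohorts the pooled mixed model finds
OR(dual vs EUT) > 1 at p < 0.05 in 45/50 replicates.

## Statistics

**Exact McNemar.** Paired binary comparisons (base vs shifted-threshold
decisions; model-vs-model agreement flags per vignette) use the exact
binomial McNemar test: with `b` and `c` discordant pairs, the two-sided
p-value is the Binomial(b + c, ½) probability of outcomes no more likely
than the observed split. The samples here are dozens of pairs with few
discordances, where the χ² approximation is unreliable. `b = c` gives
p = 1; `b = c = 0` is flagged degenerate with p = 1. The choice of an
exact paired test on agreement flags for the per-vignette model comparison
is this package's own, documented here.

**Random-intercept logit.** The pooled model comparison regresses the
agreement flag on model indicators (expected-utility as reference) with a
participant-level random intercept, fitted by maximum likelihood with
adaptive Gauss–Hermite quadrature (order 15 by default, configurable; the
per-cluster mode and curvature are found by Newton steps on the strictly
concave log-integrand). Odds ratios for regret-vs-EUT, dual-vs-EUT and
dual-vs-regret carry Wald 95% intervals on the log-odds scale. No
multiple-testing correction is applied; raw p-values are reported. The
fitter is written in numpy/scipy because the Python scientific stack has no
frequentist quadrature-based GLMM; it is cross-checked in the test suite
against `lme4::glmer` (same quadrature order) to ~10⁻⁵ agreement on
coefficients, random-intercept SD and log-likelihood, and against the
pooled logistic fit when the variance is pinned at zero. Convergence is
judged by the gradient norm; complete separation (|β| > 15) or
non-convergence triggers a documented fallback refit with an L2 penalty of
10⁻³ and sets flags on the result.

**Model ranking.** In the recovery analyses a replicate counts as
identifying the generating model when no other model attains strictly
higher agreement; ties count in favor, since the dual-processing model
reduces exactly to the expected-utility model at γ = 0 and exact agreement
ties are a structural possibility, not an artifact.

## Problem sizes and determinism

The recovery suite uses 50 replicates of 100 participants (600 responses,
1800 agreement flags per replicate) per generating model; design-gradient
checks use noise-free cohorts of 41, a customary sample size for
cognitive-psychology experiments of this kind. All
randomness flows through numpy `SeedSequence` streams spawned per purpose
(plans, marks, scales, automatic assessments, noise flips, latent labels),
so identical configurations produce byte-identical tables, and generating
models can be swapped without disturbing the other streams (a dual cohort
with a degenerate γ = 0 distribution reproduces the EUT cohort's decisions
exactly under the same seed).

## Known limitations

- The grouping ambiguity in the dual-processing formula is resolved by
  exposing both parses, not by determining the original intent.
- `H₁/H₂` mixes a subjective 0–100 regret mark with an objective harm
  magnitude; the package's convention of placing objective magnitudes on
  the same 0–100 scale makes the ratio well-scaled but is a modeling
  convention, not a measurement.
- The mixed model assumes a single random intercept per participant across
  all vignettes and models; vignette-level random effects are not modeled.
- Cohort-level odds ratios published for real physician cohorts cannot be
  reproduced without the individual-level responses, which are not publicly
  deposited, and are not targeted.
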