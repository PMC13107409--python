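# Methods

## The simulation model

Each simulated patient carries a latent linear ALSFRS-R trajectory

    m_i(t) = (β₀ + u₀ᵢ) + b₁ᵢ·t,    b₁ᵢ = (β₁ + u₁ᵢ)·(1 − δ·activeᵢ),

with `(u₀, u₁)` bivariate normal. Observed scores add residual noise, are
rounded to the instrument's integer scale and clamped to [0, 48]. Death and
non-death dropout are competing exponential times; whichever comes first
truncates follow-up and the other is cleared, mirroring how trials report
disjoint death and dropout counts. The death hazard is

    h_i = λ_death · exp(a · (−u₁ᵢ/σ_u1)) · HRᵃᶜᵗⁱᵛᵉ,

i.e., log-linear in the *standardized untreated* random slope: faster
progressors die sooner. This is the informative-truncation mechanism that
makes missing-data strategies diverge; it deliberately avoids numerical
hazard integration (constant hazards sample in closed form) while keeping
the death–progression link. Scheduled visits before truncation are
additionally missed independently with a small per-visit probability
(recoverable, "intermittent" missingness); baseline is never missed.

Treatment acts proportionally on the progression rate (`δ = 0.2` is a 20%
slowing) and optionally on the death hazard (`HR`, default 1 — a
function-only effect). Note the proportional effect also scales the random
slope, so the active arm's slope variance shrinks by `(1−δ)²`; the
mixed-model analyses assume a common slope variance, a deliberate, mild
misspecification of the kind real analyses face.

### Parameters, units, defaults

| parameter | meaning | default | unit |
| --- | --- | --- | --- |
| β₀ | mean baseline score | 38 | points |
| β₁ | mean progression rate | −0.231 | points/week (≈ −1/month) |
| σ_u0 | intercept SD | 5 | points |
| σ_u1 | slope SD | 0.18 | points/week |
| ρ | intercept–slope correlation | −0.2 | — |
| σ_e | residual SD | 2.2 | points |
| λ_death | baseline death hazard | 0.0034848 | /week |
| a | death–slope association | 0.8 | per SD of slope |
| λ_drop | dropout hazard | 0.0049415 | /week |
| p_int | per-visit intermittent miss | 0.0126958 | — |

The trajectory parameters are plausible for a 52-week phase-3 ALS
population (mean decline about one point per month from a baseline in the
high 30s). Two calibrations fix the free scale:

1. **Attrition.** `calibrate_attrition` tunes `λ_death`, `λ_drop`, `p_int`
   (in that order, cycled three times because death and dropout compete) by
   one-dimensional root-finding against the target margins — 18.1% deaths,
   20.3% dropout, 47.8% of patients missing at least one post-baseline
   assessment at n=513 over 52 weeks. Common random numbers make each margin
   a smooth monotone function of its own parameter. The frozen defaults come
   from a 400-replicate calibration run and reproduce the margins within
   about half a percentage point on fresh seeds.
2. **Power anchor.** The slope SD was set so that the design anchor holds:
   a 500-patient, 2:1-randomized trial with a 20% slowing analyzed by the
   random-slopes model has ≈80% power at two-sided α=0.05 (σ_u1 = 0.15
   gave ≈92%; 0.18 gives ≈80%). σ_e was left untouched. The attrition
   margins are invariant to this choice because the death hazard acts on
   the standardized slope.

Every stochastic mechanism (assignment, random effects, residuals, death,
dropout, intermittent missingness) draws from its own named stream spawned
from the master seed, so changing one mechanism's parameter perturbs only
its own draws. Output is bit-reproducible for a fixed seed.

### What the generator does and does not emulate

It reproduces the *margins* of a real 52-week trial — attrition levels, an
informative death process, integer scores on a bounded scale, sporadic
missed visits — under linear-in-time mean decline. It does not model
sigmoidal or floor-accelerated trajectories, time-varying hazards,
item-level (12-question) structure, site effects, or measurement practice
differences. Passing tests therefore demonstrate the *mechanisms* (e.g.,
LOCF inflating false positives under differential attrition, longitudinal
models out-powering single-visit ones), not numerical agreement with any
particular real dataset; orderings among closely matched strategies can
legitimately differ under other trajectory/hazard shapes.

## Analysis strategies

A strategy is a composition: outcome summary (change from baseline at a
visit, per-patient OLS slope, responder dichotomization, the full
longitudinal profile, all-pairs ranks, or time to 6-point decline or death)
× model (t test, linear/logistic regression, rank-sum, repeated-measures
ANOVA with Greenhouse–Geisser correction, random-intercept or random-slopes
mixed model, MMRM, log-rank, joint-rank) × baseline adjustment × one
missing-data strategy for death-caused gaps and one for non-death gaps
(intermittent gaps follow the non-death strategy). The catalog holds 23
named presets spanning every family.

Missing-data semantics:

- **complete case** leaves gaps; patients missing the analysis visit drop
  out of that analysis.
- **LOCF** carries the last observed score forward into each gap.
- **worst score** imputes the scale minimum (configurable) at and after
  death.
- **last common visit (LCV)** truncates the schedule to the latest visit at
  which every patient still alive and on study demonstrably remained under
  observation (has a recorded assessment at or after it). Reading
  availability as "the score was actually recorded at that visit" would
  make the common window collapse to baseline whenever ~500 on-study
  patients each miss a visit with even 1% probability, so sporadic skipped
  visits do not curtail the window; retention does.
- **multiple imputation** draws M=10 completed datasets by sequential
  (visit-by-visit) linear regression on arm, baseline, and all earlier
  visits, with coefficients and error variance drawn from the posterior
  under a noninformative prior; per-imputation results combine by Rubin's
  rules with Barnard–Rubin degrees of freedom.
- **implicit** leaves the data to a likelihood-based longitudinal model.

Each strategy maps deterministically to an estimand strategy for death:
worst-score/rank/time-to-event compositions → *composite*; death imputed by
a hypothetical continuation (LOCF, MI) → *hypothetical*; landmark analyses
excluding the dead → *principal stratum*; slope-type analyses of pre-death
data (random-effects models, per-patient slopes) → *while alive*. MMRM with
implicit handling is classified *hypothetical*: its target is the mean at a
landmark as if patients continued under the MAR-extrapolated trajectory,
unlike the rate-based while-alive models.

## Numerical choices

- **Mixed models** are fitted by profiled REML written for this package:
  fixed effects and the residual variance are profiled out, the scaled
  random-effect covariance is parametrized by its Cholesky factor
  (log-diagonal), and the criterion and its analytic gradient reduce to 2×2
  algebra per patient via the Woodbury identity. One fit at n≈500 takes
  ~0.1 s, which is what makes 500-permutation nulls affordable; tests pin
  the solver against statsmodels' MixedLM on small datasets (agreement to
  ~1e-4 relative on coefficients) and require at-least-as-good REML criteria
  on draws where the reference optimizer fails. Wald tests use the normal
  reference.
- **MMRM** is maximum likelihood for the multivariate-normal regression of
  post-baseline change-from-baseline on visit-specific intercepts and arm
  effects plus a common baseline slope, with unstructured within-patient
  covariance, maximized by EM over missingness patterns (ignorable
  missingness). A REML-style scale correction (`n/(n − q/k)`) makes the
  single-complete-visit case reproduce the ANCOVA variance exactly. When
  patients are too few for an unstructured covariance the fit falls back to
  compound symmetry with a warning.
- **Greenhouse–Geisser**: ε = (tr Σc)²/((k−1)·tr Σc²) with Σc the pooled
  within-arm covariance of orthonormalized visit contrasts; both degrees of
  freedom of the arm×visit interaction F are multiplied by ε. Cross-checked
  against pingouin's mixed ANOVA.
- **Rank tests** use exact enumeration for small untied samples and the
  tie- and continuity-corrected normal approximation otherwise (scipy). The
  joint-rank score compares survival to the landmark first (later death or
  survival wins), then change from baseline (last available value when the
  landmark is missed); missing-vs-missing functional comparisons score 0.
- **Log-rank** accumulates hypergeometric observed-minus-expected terms
  in-package (the signed z needs the O−E direction; the estimate is the
  Peto log hazard ratio (O−E)/V); p-values are cross-checked against
  lifelines.
- **Wilson intervals** wrap statsmodels' score interval with exact 0/1
  endpoints at 0 or n successes.
- Internal p→z conversions clamp p at 1e-300 to keep the quantile finite;
  degenerate fits (zero variance with equal means, all-tied ranks) return
  p=1 rather than erroring, matching the permutation engine's needs.

## The evaluation engine

False-positive rates come from label permutation on a fixed synthetic
master dataset: arm labels are reassigned at the original 2:1 sizes, so
both "arms" are draws from one population and any rejection is the
method's fault. Power uses the same permutation plus an injected slowing:
each active patient's post-baseline change is rescaled,
`y(t) → y(0) + (1−δ)(y(t)−y(0))`, rounded and clamped — the injection acts
on observed trajectories, leaving death/dropout untouched (a function-only
effect). The differential-attrition scenario raises the active arm's
*non-death dropout* rate to 40% (the scale on which trial reports quote
group attrition; the pre-existing rate is ≈20%) by drawing new dropout
times uniformly over post-baseline visits. Model-based simulation under the
alternative (including a death hazard ratio) is available through the
generator for sensitivity analyses of composite endpoints.

A strategy is *valid* when its null rate is ≤ 0.10 (twice the nominal
two-sided 0.05 — a tolerance for Monte-Carlo and small-sample slack, not a
test level). Fit failures are excluded from the rate denominator and
counted; a cell aborts beyond 20% failures. Per-cell random streams derive
from the master seed and the strategy/scenario names, so grids are
reproducible cell-by-cell.

Problem sizes: the packaged defaults run 1,000 replicates per cell; the
test suite and the acceptance script use 100–500 permutations and 400
simulated trials per estimate, sizes at which Wilson intervals on the
reported rates are a few percentage points wide.

## Known limitations

- The generator's linear trajectories and constant hazards are a
  deliberate simplification; power *orderings among composite endpoints*
  are sensitive to them. In this package's conditions the 6-point-decline
  threshold is crossed by most patients and a 20% slowing delays the
  crossing almost deterministically, so the time-to-event log-rank retains
  moderate power while rank- and responder-based composites (which mix in
  effect-free survival comparisons or discard magnitude information) sit
  lower — the composite group as a whole remains the weakest estimand
  family, but the worst single composite differs from what analyses of
  real, noisier trial data can show.
- The proportional-rescaling injection shrinks within-patient measurement
  noise by the same factor as the signal; with residual SD well below the
  between-patient slope spread this is second-order.
- MMRM standard errors ignore the uncertainty of the estimated covariance
  (the usual practice); no small-sample (Kenward–Roger-type) correction is
  offered, and mixed-model tests use the normal reference throughout — the
  permutation engine measures the realized type-I error anyway, which is
  the package's point.
- Multiple imputation conditions on arm, baseline, and earlier visits only;
  auxiliary covariates are not modeled (the generator produces none).
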