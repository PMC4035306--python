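# Methods

## The persistence problem and the two models

A declining species' current distribution is a subset of its known
historical distribution. Classifying each historically occupied site as
*persisted* (1) or *extirpated* (0) turns persistence into a binary
site outcome — but one observed with asymmetric error: a detection is
essentially never wrong, while a non-detection may be a true absence or
a miss.

Two models address this at different levels of ambition.

**Latent selection difference (LSD).** Both site sets were "selected"
by the species historically; what differs is whether the population
survived. Logistic discrimination of the two sets gives coefficients
β, and the exponential score w(x) = exp(Σ βₖxₖ) is proportional to the
probability of persistence. Proportional only: the sampling of the two
classes fixes the intercept, so the intercept is estimated (it is
needed for the likelihood) but excluded from the score, and all
downstream use of LSD scores is through ratios or correlations.
Detection error is ignored; a never-detected site is treated as
extirpated.

**Detection-corrected persistence.** With K repeat visits per season,
the single-season occupancy likelihood separates persistence ψ from
per-visit detection p:

    L_i = ψ_i ∏_{j∈surveyed} p_ij^{y_ij}(1−p_ij)^{1−y_ij}
          + (1−ψ_i)·I[no detection among surveyed occasions].

Assumptions: (1) closure — a site's persistence state does not change
across the season's visits; (2–3) ψ and p constant across sites *or
modeled* through covariates (ψ logit-linear in site covariates, p
logit-linear in site or visit covariates); (4) detections independent
across visits given the state; and no false positives. Unsurveyed
occasions contribute likelihood factor 1; a never-surveyed site
contributes exactly 1 and is retained (with a warning) so the site
count used by AICc stays fixed.

## Estimation

Both likelihoods are maximized with BFGS from a zero start, with up to
five seeded jittered restarts on failure. The detection model uses an
analytic score; convergence is accepted when the optimizer reports
success or the gradient norm is below 1e-4·(1+|nll|) — near a
probability boundary (p̂ → 1 under near-perfect detection) line-search
precision loss is routine while the score is genuinely flat.
Standard errors come from the inverse observed information (analytic
X'WX for the logistic; numerical Hessian for the detection model), and
the Hessian condition number is reported so ranking can exclude
ill-behaved structures (threshold 1e8). A fitted probability within
1e-6 of 0/1 sets `boundary_flag`.

Separation in the LSD fit is flagged (not raised) when any |slope|
exceeds 15 on the logit scale — odds ratios beyond e¹⁵ are numerically
indistinguishable from infinity at this scale. The bound deliberately
ignores the intercept, which legitimately grows when a covariate is
location-shifted.

Occasion-level detection covariates (e.g. Julian date, range ~140–235)
are standardized to mean 0, SD 1 over surveyed cells before fitting;
coefficients are reported on both the standardized and natural scales
with the scaling stored on the fit for prediction.

## Covariate preparation and screening

Log transforms use ln(x + c) with c = half the smallest positive
observed value (c = 1 for an all-zero covariate); c is recorded so the
transform is invertible and reproducible. Screening computes pairwise
Pearson correlations among candidates; for each pair with |r|
*strictly* above 0.65 (processed greedily from the largest |r| down),
the member with the worse single-covariate AICc against the persistence
labels is dropped; score ties within 1e-6 are broken alphabetically.
Zero-variance covariates are excluded from screening with a warning.

## Model selection

AICc uses effective sample size n = number of sites, the standard
convention for single-season likelihoods where each site is one
independent term. Non-converged and ill-conditioned fits are excluded
with recorded reasons; exact AICc ties order by smaller K, then name.
Akaike weights are normalized over the full included candidate set,
not over any displayed subset.

The built-in persistence candidate set has 13 ψ-structures (singles,
combinations, a global model, a null). It intentionally contains the
bulrush covariate twice — once as a vegetation-category model and once
as a buffer-category model — mirroring the a-priori design it encodes;
the two entries share the term but keep distinct names, and the
pipeline deduplicates structures before crossing with the four
detection structures p(.), p(Rush), p(Date), p(Rush+Date). The "top
models carried forward" rule is ΔAICc ≤ 4 capped at four models, both
configurable.

One known wrinkle: a published ranking of this kind can print −2LL and
K columns that are mutually inconsistent with the ΔAICc column under
the standard AICc formula at n = 43. This package always derives ΔAICc
from the formula; it makes no attempt to reproduce any table's internal
arithmetic beyond the exp(−Δ/2) identity, which is exact.

## Goodness-of-fit

Sites are grouped into cohorts by their pattern of surveyed occasions;
within a cohort each possible 0/1 history is a cell, with expected
count Σᵢ P(history | ψ̂ᵢ, p̂ᵢⱼ). Expected counts conserve cohort totals
exactly. Cells with expected count < 0.5 are pooled into one
cohort-level "other" cell before the Pearson sum — at ~43-site scale
most 3-visit cells are small and the statistic is unstable without
pooling. The null distribution comes from a parametric bootstrap
(default 1000 replicates): simulate histories from the fitted model
preserving each site's missingness pattern, refit the same structure
warm-started at the original estimates, recompute the statistic.
p = share of bootstrap statistics ≥ observed (observed not added to
the null sample); ĉ = observed / bootstrap mean. Replicates whose
refit fails are dropped and counted; > 20% failures attaches an
"unreliable" warning.

A note on what inflates ĉ: cell-count *means* depend on ψ only through
its site average, so unmodeled site-to-site variation in ψ alone cannot
inflate the Pearson statistic — it provably shrinks the count variance
(mean ĉ ≈ 0.85 vs ≈ 0.98 homogeneous in our replicate experiments).
Overdispersion detectable by this test comes from heterogeneity on the
detection side (mean ĉ ≈ 2.4 with an unmodeled site effect on p), and
that is how the heterogeneity property is exercised in the test suite.

## The simulator

`simulate_dataset` draws covariates from declared distributions, latent
persistence zᵢ ~ Bernoulli(logit⁻¹(xᵢ'β)), detections
yᵢⱼ = zᵢ·Bernoulli(logit⁻¹(vᵢⱼ'α)) on surveyed occasions (no false
positives), and masks occasions missing-completely-at-random. The
default "grebe-like" configuration encodes the study design this
package is aimed at: 43 sites, 3 occasions, Develop ~ Beta(1,6),
Forest ~ Beta(3,3), Rush ~ Beta(1.5,6) (proportions), Fish ~
Poisson(6) (species count), Shore ~ Uniform(9,150) km (range matching
the smallest and largest surveyed perimeters; no true effect, present
so the full 13-model candidate set is estimable), Date ~
Uniform(140,235) (late May–late August). True coefficients: ψ
intercept 0.4 with Develop +2.0, Rush +3.0, Forest −1.5 (mean ψ ≈
0.62); p intercept 1.0 with Rush −1.0 (mean p ≈ 0.69); missing rate
0.1. Signs follow the field expectation (development and bulrush favor
persistence, boreal-forest surroundings disfavor it, bulrush conceals
birds from observers); magnitudes are fixture choices.

What the simulator does *not* emulate: spatial correlation among lakes,
covariate-dependent missingness, observer effects, false positives,
year-to-year dynamics, and covariate measurement error. Passing
recovery and GoF tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to their violation.

## Problem sizes used in checks

Grid-search oracles use a 40-site, 3-occasion fixture with a 0.001
probability grid (detection model) and a 20-site fixture with a 0.01
coefficient grid over [−10, 10] (LSD). Recovery uses 200 replicates at
500 sites; GoF self-consistency uses 200 bootstrap replicates at 500
sites, with the p-value calibration check run at 200 sites across 50
datasets. These sizes make the Monte-Carlo error small relative to the
asserted tolerances while keeping the full suite quick on one CPU.

## Known limitations

- No penalized (Firth) regression: separation is flagged, not
  resolved; at ~43 sites quasi-separation of a strong covariate is a
  real occurrence and such fits are excluded from ranking.
- No model averaging, no quasi-AICc re-ranking under ĉ > 1.
- No multi-season (colonization/extinction) dynamics; persistence is a
  single terminal contrast against the historical baseline.
- The bootstrap GoF inherits the usual caveat that its power at n ≈ 43
  is modest; a non-significant result is compatibility, not proof of
  fit.
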