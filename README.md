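# persistlsd

Modeling **population persistence** at historically occupied sites, for
ecologists monitoring a declining species: given a set of sites a
population once occupied, which still hold it today, and what site
attributes separate the survivors from the extirpations?

The motivating design is a waterbird survey of ~43 historically
occupied lakes, each visited up to three times in one season, with
site covariates (shoreline development, surrounding forest, emergent
bulrush, fish species richness, shoreline length) and a per-visit
covariate (Julian date).

## What it computes

**Latent selection difference (LSD).** Persisted (1) and extirpated (0)
sites are contrasted by logistic discrimination; the exponential form

    w(x) = exp(β₁x₁ + … + βₙxₙ)

is proportional to the probability of persistence, so only ratios of
scores between sites are meaningful (the logistic intercept is
estimated but excluded from the score). Covariate preparation includes
a recorded-offset natural-log transform and pairwise collinearity
screening: for |r| > 0.65 the member with the worse single-variable
AICc is dropped.

**Detection-corrected persistence.** Repeat surveys let persistence ψ
be separated from per-visit detection p. With ψᵢ = logit⁻¹(xᵢ'β) and
pᵢⱼ = logit⁻¹(vᵢⱼ'α), each site contributes

    Lᵢ = ψᵢ ∏ⱼ pᵢⱼ^yᵢⱼ (1−pᵢⱼ)^(1−yᵢⱼ) + (1−ψᵢ)·I[no detection]

with unsurveyed occasions contributing factor 1. Maximum likelihood by
quasi-Newton with analytic gradient; SEs from the inverse observed
information.

**Model selection.** AICc = −2logL + 2K + 2K(K+1)/(n−K−1) with n =
number of sites; ΔAICc, model likelihood exp(−Δ/2), and Akaike weights
over the candidate set. A fixed 13-model a-priori persistence set and a
4-structure detection crossing are built in.

**Goodness-of-fit.** Parametric-bootstrap Pearson test on detection-
history frequencies (grouped by missingness cohort, small cells
pooled), with ĉ = observed statistic / bootstrap mean as an
overdispersion diagnostic.

**Simulation.** A generator that emulates the study design end-to-end
(latent persistence → detections → missed visits), used by the tests
and available for power/recovery experiments.

## Worked example

```python
from persistlsd import (ModelSpec, fit_occupancy, grebe_like_config,
                        naive_estimate, predict_psi, rank_models,
                        simulate_dataset)

histories, covariates, _ = simulate_dataset(grebe_like_config(seed=11))
specs = [ModelSpec.build([], []), ModelSpec.build(["Develop"], []),
         ModelSpec.build(["Develop"], ["Rush"]),
         ModelSpec.build(["Develop", "Forest"], ["Rush", "Date"])]
fits = [fit_occupancy(histories, covariates, s) for s in specs]
table = rank_models(fits, n=histories.n_sites)
print(table.frame[["model", "K", "dAICc", "model_likelihood", "weight"]])
```

prints (run as `python examples/03_detection_model_and_ranking.py`):

```
                           model  K  dAICc  model_likelihood  weight
                     psi(.) p(.)  2  0.000             1.000   0.632
               psi(Develop) p(.)  3  2.145             0.342   0.216
psi(Develop+Forest) p(Rush+Date)  6  4.087             0.130   0.082
            psi(Develop) p(Rush)  4  4.411             0.110   0.070
```

On this 43-lake draw the intercept-only model wins (at n = 43 a real
covariate effect often does not repay its AICc penalty), the naive
persistence share is 0.581, and the detection-corrected mean ψ̂ is
0.597 — the correction reallocates lakes that were missed on every
visit back to the persisting side. The other scripts in `examples/`
walk through the naive-vs-true gap, LSD fitting and screening, the
bootstrap GoF, and the full four-stage pipeline; the `persistlsd` CLI
(`simulate`, `lsd`, `fit`, `rank`, `gof`, `compare`, `run`) exposes the
same steps from a shell.

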