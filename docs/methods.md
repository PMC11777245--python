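# Methods

## Model and likelihood

The core model is the Cormack–Jolly–Seber (CJS) model for open populations:
each marked individual's encounter history is conditioned on its first
capture, apparent survival φ_t applies to interval t→t+1 and detection p_t
to occasion t, and the latent alive/dead trajectory is marginalized exactly
with the χ recursion (χ_t = probability an animal alive at t is never seen
again). "Apparent" survival confounds mortality with permanent emigration;
nothing in the package attempts to separate them. Occasions with no
sampling effort keep their place in the calendar with p fixed to exactly
zero, so survival is always modeled per single year even across multi-year
gaps — never as lumped intervals.

All computation is in log space; log χ is accumulated with `logaddexp`.
Per species, the data enter the likelihood only through four count vectors
(intervals traversed; detections and non-detections between first and last
capture per occasion; last-capture counts), which makes one likelihood
evaluation O(T) regardless of sample size. Per-individual ("pointwise")
log-likelihood components are retained for every posterior draw because
leave-one-out cross-validation and ANODEV consume them.

Covariate alignment: survival over interval (year t → t+1) uses the
dry-season covariate of year t — the dry season the bird must survive.
The opposite convention (year t+1) is available via
`ModelSpec(covariate_alignment="end")`; nothing downstream depends on the
choice beyond the labeling of derived annual survival.

Identifiability: with both φ and p time-dependent, the terminal φ_{T−1}·p_T
product is only jointly identified. This standard CJS confounding is left
as-is; the uniform priors keep the posterior proper and the affected
parameters are simply wide.

## Priors and hierarchy

Species survival intercepts α_s and climate slopes β_s are partially
pooled: Normal(μ, σ) with flat (improper) priors on the global means and
flat positive priors on the spreads; detection probabilities are species
specific with Uniform(0,1) priors and no pooling. A weakly-informative
proper alternative (μ ~ N(0,10), σ ~ HalfNormal(5)) is available via
`prior_scheme="weak"` for users uncomfortable with improper hyperpriors;
with 29 species the two give practically identical posteriors. For the
time-dependent-survival model each per-interval φ_{s,t} is a free
parameter with a Uniform(0,1) prior and no pooling.

The sampler works in the centered parameterization (α_s directly, not
deviations); the posterior is identical to the non-centered one up to the
reparameterization identity, and the draws store the standardized
deviations z = (α_s − μ_α)/σ_α alongside, so either bookkeeping can be
reconstructed exactly. The centered/non-centered equivalence is asserted
in the test suite.

## Sampling

`sample_posterior` runs an adaptive Metropolis-within-Gibbs scheme chosen
to exploit two structural facts: species blocks are conditionally
independent given the hyperparameters, and the hyperparameters are
conditionally conjugate under the flat priors.

- Each unconstrained coordinate (α_s, β_s, logit p_s, logit φ_{s,t}) is
  updated with a Gaussian random-walk proposal for *all species at once*
  in one vectorized likelihood evaluation; acceptance is per species.
- Step sizes adapt per coordinate during warmup only (Robbins–Monro toward
  a 0.44 acceptance rate) and are frozen afterwards, preserving detailed
  balance in the sampling phase.
- Hyperparameters are refreshed by exact Gibbs draws: μ | σ, α ~
  Normal(mean(α), σ²/S) and σ² | μ, α ~ InvGamma((S−1)/2, Σ(α_s−μ)²/2).
  Under the weak prior scheme they are updated by a short Metropolis sweep
  instead.

Defaults are 4 chains × 1000 warmup + 1000 kept sweeps; chains run
sequentially from over-dispersed random starts, fully determined by the
seed (a PCG64 stream per chain via `SeedSequence.spawn`). The test suite
and the acceptance script use 2 chains × 300–500/300–500 because the
sampler mixes adequately there for the global parameters; users estimating
per-species tail quantities should use the larger defaults. Convergence QC
(split-R̂ < 1.01, bulk ESS ≥ 400 by default, both configurable) is reported
by `convergence_check`, which delegates the diagnostics to arviz; a single
chain yields an explicitly partial (ESS-only) report.

## Model selection and ANODEV

ELPD is estimated by Pareto-smoothed importance-sampled LOO with the
individual encounter history as the pointwise unit (the natural
exchangeable unit here). The Pareto smoothing of the importance weights is
delegated to `arviz.psislw`; the ELPD sum, its standard error
√(n·var(elpd_i)), pairwise difference SEs and the k̂ > 0.7 reliability
flags are computed in `selection.elpd_loo` / `compare_models`. At least
100 draws are required for the generalized-Pareto tail fit. A climate
covariate is declared "important" when its model's ELPD exceeds that of
every climate-free (null) model; exact ties rank the less complex model
first.

The ANODEV fraction [−2lnL(φ·) + 2lnL(φ_CLIMATE)] / [−2lnL(φ·) + 2lnL(φ_t)]
is evaluated per draw with the three models' draws paired by flattened
(chain, iteration) index — an arbitrary but reproducible coupling of
independently fitted posteriors — and summarized by the median. Draws with
a near-zero denominator (|·| < 1e−8 by default) are dropped and counted.
Both a pooled community version (total log-likelihoods) and a per-species
version (species log-likelihood components, medians averaged across
species) are provided; the per-species average is the default community
summary. The per-draw fraction is not confined to [0, 1]: an
overparameterized time model can sit below the climate model in posterior
log-likelihood, pushing individual draws past 1.

## Derived climate impacts

`community_climate_impact` converts a raw covariate shift (°C or mm) into
standardized units with the climate series' reference-window standard
deviation and evaluates, per draw, the percent reduction from
φ0 = logistic(μ_α) to φ1 = logistic(μ_α + μ_β·Δz). The baseline is thus the
community mean at the covariate mean (z = 0) using the global
hyper-means — one explicit convention among several defensible ones; a
per-species average is available by applying `percent_reduction` to
per-species survival draws. Percent reductions are always computed per
draw and then summarized (posterior mean), never on rounded point
estimates.

## Climate covariates

Covariates are yearly dry-season means (June–November by default,
configurable); z-transformation uses the sample standard deviation
(denominator n−1) over an explicit reference-year window, defaulting to
the occasion years of the capture data. Values outside the window are
standardized with the same constants, so either convention — standardizing
over the capture period or over a longer reanalysis period — is
reproducible by passing the appropriate `reference_years`. Sub-annual
records are reduced by mean-of-daily values per dry season in the
`aggregate_dry_season` helper. Extreme-year identification breaks ties
toward the earliest year.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the scale of a long-running Amazonian understory banding program:
29 species, 27 annual occasions, a Poisson release schedule averaging
6.2 new individuals per species per sampled year (~4300 individuals with
three unsampled years), baseline annual survival near 0.57 (logit
intercept 0.3, spread 0.5), a global temperature slope of −0.5 per sd with
spread 0.15, and species detection probabilities around 0.45. The climate
is a warming (+0.035 °C/yr) and drying (−0.37 mm/yr) dry season whose
noise pair is bivariate normal with the noise correlation solved so the
overall temperature–precipitation Pearson correlation is −0.86 in
expectation. Survival is driven by one covariate (temperature by
default); the strong collinearity then induces the mirrored positive
precipitation effect, as in real data.

What the generator does *not* emulate: individual heterogeneity in
survival or detection, trap response, site structure (transects are pooled
exactly as the single-population analysis assumes), age structure beyond
an optional transient mixture (default 0, reflecting upstream removal of
juveniles), density dependence, and recruitment dynamics. Passing
recovery/selection tests on these data therefore demonstrates correctness
of the estimation machinery under the model's own assumptions, not
robustness to their violation. The optional transient fraction and the
`lifespan_slope` coupling (species slopes linear in baseline survival)
exist to probe specific departures.

All simulation is deterministic given the seed; the truth ledger records
species parameters, per-year rates and the full latent alive matrix so
tests can check empirical frequencies against configured probabilities.

## Numerical and design choices

- Zero-count sufficient-statistic terms are masked so 0·(−∞) never
  contaminates a likelihood; a −∞ log term with a positive count correctly
  yields −∞.
- Weighted least squares (capture-weighted life-span regressions) uses the
  standard weighted normal equations via statsmodels WLS: slope SE from
  the weighted residual variance with n−2 df, two-sided t p-value,
  R² about the weighted mean. With equal weights this is OLS exactly, and
  with integer weights it matches OLS on row-replicated data for the
  fitted line and R² (degrees of freedom, hence SEs, differ by design).
  Baseline survival enters on the probability scale, and posterior medians
  (not means) summarize both predictor and response.
- The two regressions' variance explained is reported per regression plus
  their mean, since a single "percent of variance" spanning both fits is
  otherwise ambiguous.
- Individuals first captured at the final occasion contribute a likelihood
  factor of 1; they are retained rather than dropped.
- Reused band numbers across species are a hard error, never merged.
- Pipeline runs are summarized in a manifest (config hash, seed, package
  version, per-stage outputs with SHA-256 checksums); stages are cached by
  config hash with an explicit `--force` override.

## Known limitations

- The life-span regression treats posterior medians as known quantities;
  shrinkage of the species slopes and error in the baseline-survival
  predictor attenuate the fitted coefficient when per-species data are
  sparse (visible in the recovery test, which uses a data-rich scenario).
  An errors-in-variables treatment is deliberately out of scope.
- Additive or interactive temperature × precipitation survival models are
  not offered as primary outputs: with collinearity near −0.86 they are
  not robustly estimable, which is precisely why the candidate set treats
  the two covariates as alternative single-covariate models.
- The Metropolis-within-Gibbs sampler mixes more slowly than a tuned HMC
  implementation for strongly correlated per-species blocks; effective
  sample sizes per sweep are modest, which is compensated by the very low
  cost per sweep.
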