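# cjsclim

Hierarchical Bayesian Cormack–Jolly–Seber (CJS) models of climate-driven
apparent survival in marked animal communities, built for multi-species
bird banding studies where yearly dry-season severity (temperature,
precipitation) is the hypothesized driver of adult survival.

The package is aimed at capture–mark–recapture practitioners who want a
tested, scriptable workflow for the whole analysis chain: climate covariate
preparation, encounter-history handling, exact marginalized CJS likelihoods,
partial-pooling Bayesian estimation across species, PSIS-LOO model
comparison, analysis-of-deviance (ANODEV) attribution of temporal survival
variation to climate, derived community-level climate impacts, and
capture-weighted life-span sensitivity regressions — all exercisable on
synthetic communities with known ground truth.

## The model

For individual *i* of species *s*, detections over annual occasions
*t* = 1…T form an encounter history conditioned on first capture. The CJS
likelihood marginalizes the latent alive/dead process with the χ recursion

```
χ_T = 1,    χ_t = (1 − φ_t) + φ_t (1 − p_{t+1}) χ_{t+1}
```

where φ_t is apparent survival over interval t→t+1 and p_t the detection
probability at occasion t (fixed to 0 in years without netting). Climate
models make survival logit-linear in a z-scored dry-season covariate x_t:

```
logit(φ_{s,t}) = α_s + β_s x_t
α_s ~ Normal(μ_α, σ_α),   β_s ~ Normal(μ_β, σ_β)      (partial pooling)
p_{s} ~ Uniform(0, 1)                                  (no pooling)
```

with flat priors on the global means and flat positive priors on the
spreads. The candidate set crosses time-dependent/independent φ and p with
temperature- or precipitation-dependent φ; models are compared by
Pareto-smoothed importance-sampled leave-one-out cross-validation (ELPD),
and the share of temporal deviance explained by climate is the ANODEV
fraction `[−2lnL(φ·) + 2lnL(φ_CLIMATE)] / [−2lnL(φ·) + 2lnL(φ_t)]`
computed per posterior draw and summarized by its median.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme
purpose-built for this structure (conjugate Gibbs updates for the
hyperparameters, vectorized componentwise random-walk updates across
species); a community-scale fit (29 species × 27 years × ~4300 birds)
takes about a second per thousand sweeps on one CPU. See
`docs/methods.md` for assumptions, parameter conventions and limitations.

## Worked example

```python
import numpy as np
import cjsclim as cc

# a community-scale synthetic dataset with known truth
bundle = cc.make_paper_scale_scenario(seed=1)
print(f"{bundle.matrix.n_individuals} individuals, "
      f"{len(bundle.matrix.species_list())} species, "
      f"{bundle.matrix.n_occasions} occasions")
print(f"temperature-precipitation correlation: "
      f"{cc.climate_correlation(bundle.climate):.3f}")

fit = cc.sample_posterior(
    bundle.matrix, cc.ModelSpec("temperature"), bundle.climate,
    chains=2, warmup=500, draws=500, seed=2,
)
mu_beta = fit.flat("mu_beta")
lo, hi = np.percentile(mu_beta, [2.5, 97.5])
print(f"global temperature effect: {mu_beta.mean():.3f} "
      f"(95% CrI {lo:.3f} to {hi:.3f}; truth -0.5)")

impact = cc.community_climate_impact(fit, raw_shift=1.0)
print(f"+1 degree C: {impact.percent:.1f}% reduction in community-mean "
      f"survival (95% CrI {impact.ci95[0]:.1f} to {impact.ci95[1]:.1f})")
```

prints

```
4331 individuals, 29 species, 27 occasions
temperature-precipitation correlation: -0.829
global temperature effect: -0.497 (95% CrI -0.604 to -0.397; truth -0.5)
+1 degree C: 62.9% reduction in community-mean survival (95% CrI 52.6 to 71.9)
```

The generator drew species survival intercepts and temperature slopes from
a hierarchy with global slope −0.5 on the logit scale per standard
deviation of dry-season temperature; the fitted posterior recovers that
value, and converting it to a raw +1 °C shift at the community-mean
baseline yields the percent survival reduction.

The same workflow is available from the shell:

```
cjsclim simulate --seed 1 --out run/data
cjsclim fit --data run/data/captures.csv --calendar run/data/calendar.csv \
        --climate run/data/climate.csv --model temp --seed 2 --out run/fit_temp
cjsclim run-all --seed 1 --out run/full     # simulate -> fit -> select -> ...
```

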