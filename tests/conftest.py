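"""Shared fixtures: small hand-built datasets and session-scoped experiments.

The expensive simulation experiments (replicate fits at community scale) are
computed once per session and shared between the unit-level checks and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cjsclim as cc


@pytest.fixture(scope="session")
def small_calendar() -> cc.OccasionCalendar:
    return cc.OccasionCalendar.all_sampled([2000, 2001, 2002, 2003])


@pytest.fixture(scope="session")
def small_climate() -> cc.ClimateSeries:
    series = cc.ClimateSeries(
        years=np.array([2000, 2001, 2002, 2003]),
        temp_c=np.array([25.0, 26.5, 26.0, 27.5]),
        precip_mm=np.array([320.0, 290.0, 300.0, 260.0]),
    )
    return cc.zscore_covariates(series)


@pytest.fixture(scope="session")
def small_matrix(small_calendar) -> cc.CaptureHistoryMatrix:
    detections = np.array(
        [
            [1, 1, 0, 1],
            [1, 0, 1, 0],
            [0, 1, 1, 1],
            [0, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 1, 1],
        ]
    )
    return cc.CaptureHistoryMatrix(
        individuals=np.array([f"b{i}" for i in range(6)]),
        species=np.array(["A", "A", "A", "B", "B", "B"]),
        detections=detections,
        calendar=small_calendar,
    )


@pytest.fixture(scope="session")
def paper_scale_bundle() -> cc.ScenarioBundle:
    return cc.make_paper_scale_scenario(1)


@pytest.fixture(scope="session")
def recovery_experiment():
    """20 replicate community-scale temperature fits with known truth.

    Truth: the generator's global temperature effect mu_beta = -0.5.
    Returns per-replicate 95% credible intervals for mu_beta.
    """
    intervals = []
    for rep in range(20):
        bundle = cc.make_paper_scale_scenario(100 + rep)
        fit = cc.sample_posterior(
            bundle.matrix,
            cc.ModelSpec("temperature"),
            bundle.climate,
            chains=2,
            warmup=400,
            draws=400,
            seed=500 + rep,
        )
        mb = fit.flat("mu_beta")
        lo, hi = np.percentile(mb, [2.5, 97.5])
        intervals.append((lo, hi))
    return {"truth": -0.5, "intervals": intervals}


def _selection_replicate(mu_beta: float, sigma_beta: float, seed: int) -> bool:
    """One model-selection replicate; True iff temperature is flagged important."""
    cfg = cc.SimulationConfig(
        n_species=10,
        n_occasions=15,
        start_year=1990,
        mean_releases_per_year=6.0,
        mu_beta=mu_beta,
        sigma_beta=sigma_beta,
    )
    rng = np.random.default_rng(seed)
    climate = cc.simulate_climate(cfg, rng)
    matrix, _ = cc.simulate_capture_histories(cfg, climate, rng)
    kw = dict(chains=2, warmup=300, draws=300, seed=seed + 1000)
    loo = {}
    for name, spec in [
        ("phi(.)p(.)", cc.ModelSpec("constant")),
        ("phi(t)p(.)", cc.ModelSpec("time")),
        ("phi(temp)p(.)", cc.ModelSpec("temperature")),
    ]:
        fit = cc.sample_posterior(matrix, spec, climate, **kw)
        loo[name] = cc.elpd_loo(fit)
    return cc.compare_models(loo).important["temp"]


@pytest.fixture(scope="session")
def selection_experiment():
    """10 replicates each with a strong and a null generating climate effect."""
    strong = sum(_selection_replicate(-0.5, 0.1, 7000 + r) for r in range(10))
    null = sum(_selection_replicate(0.0, 0.0, 9000 + r) for r in range(10))
    return {"strong_wins": strong, "null_wins": null, "n": 10}
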