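"""Hierarchical Bayesian estimation of the community CJS model.

Species share a survival hierarchy: on the logit scale each species' survival
intercept ``alpha_s`` and (for climate models) slope ``beta_s`` are drawn from
global normal distributions with means ``mu_alpha, mu_beta`` and spreads
``sigma_alpha, sigma_beta`` (partial pooling). Detection probabilities are
species-specific with uniform priors and no pooling, fixed to zero in
unsampled years. Global means carry flat priors and the spreads flat priors
on the positive half-line (a weakly-informative proper alternative is
available via ``prior_scheme="weak"``).

Sampling uses an adaptive Metropolis-within-Gibbs scheme that exploits the
model's structure: conditional on the hyperparameters the species blocks are
independent, so each logit-scale coordinate is updated for *all* species
simultaneously with componentwise random-walk proposals (step sizes adapted
during warmup only), while the hyperparameters are refreshed by their exact
conjugate conditionals (normal for the means, inverse-gamma for the squared
spreads). The centered parameterization used internally targets the same
posterior as the non-centered one; species deviations ``z = (alpha - mu) /
sigma`` are stored with the draws so either bookkeeping can be reconstructed
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .capture import CaptureHistoryMatrix, OccasionCalendar
from .climate import ClimateSeries, celsius_to_z, mm_to_z
from .likelihood import (
    ModelSpec,
    SpeciesLikelihood,
    interval_covariate,
)

__all__ = [
    "PosteriorDraws",
    "CommunityLikelihood",
    "log_posterior",
    "sample_posterior",
    "derived_annual_survival",
    "percent_reduction",
    "community_climate_impact",
    "ImpactResult",
    "convergence_check",
    "ConvergenceReport",
]

logger = logging.getLogger(__name__)

_TARGET_ACCEPT = 0.44  # componentwise random-walk optimum


class CommunityLikelihood:
    """Stacked per-species sufficient statistics for the whole community.

    ``loglik_all`` evaluates every species' CJS log-likelihood in one
    vectorized pass; the per-species :class:`SpeciesLikelihood` objects are
    kept for pointwise (per-individual) log-likelihoods.
    """

    def __init__(self, matrix: CaptureHistoryMatrix):
        self.calendar = matrix.calendar
        self.species = matrix.species_list()
        self.rows = [np.flatnonzero(matrix.species == sp) for sp in self.species]
        self.per_species = [
            SpeciesLikelihood(matrix.detections[r], matrix.calendar.sampled)
            for r in self.rows
        ]
        self.S = len(self.species)
        self.T = matrix.n_occasions
        self.n_individuals = matrix.n_individuals
        self.A = np.stack([sl.A for sl in self.per_species])  # (S, T-1)
        self.D = np.stack([sl.D for sl in self.per_species])  # (S, T)
        self.N = np.stack([sl.N for sl in self.per_species])
        self.C = np.stack([sl.C for sl in self.per_species])

    def loglik_all(self, phi: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Log-likelihood per species for (S, T-1) phi and (S, T) p."""
        with np.errstate(divide="ignore"):
            lphi = np.log(phi)
            lp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
            l1mp = np.log1p(-p)
        S, T = p.shape
        logchi = np.zeros((S, T))
        with np.errstate(divide="ignore"):
            l1mphi = np.log1p(-phi)
        for t in range(T - 2, -1, -1):
            logchi[:, t] = np.logaddexp(
                l1mphi[:, t], lphi[:, t] + l1mp[:, t + 1] + logchi[:, t + 1]
            )
        # mask zero counts so 0 * (-inf) never poisons the sum; a -inf log
        # term with a positive count correctly drives the total to -inf
        def dot(w, lg):
            with np.errstate(invalid="ignore"):
                return np.where(w > 0, w * lg, 0.0).sum(axis=1)

        return dot(self.A, lphi) + dot(self.D, lp) + dot(self.N, l1mp) + dot(
            self.C, logchi
        )


class _Layout:
    """Index bookkeeping for the per-species unconstrained parameter block."""

    def __init__(
        self,
        spec: ModelSpec,
        calendar: OccasionCalendar,
        climate: ClimateSeries | None,
        S: int,
        pooling: bool,
    ):
        self.spec = spec
        self.T = calendar.n_occasions
        self.sampled = calendar.sampled
        if spec.phi_structure == "constant":
            self.n_phi = 1
        elif spec.is_climate:
            self.n_phi = 2
            if climate is None or not climate.standardized:
                raise ValueError("climate model needs a standardized climate series")
        else:  # time
            self.n_phi = self.T - 1
        self.x = (
            interval_covariate(spec, climate, calendar) if spec.is_climate else None
        )
        # detection parameters: occasions 2..T that were sampled (occasion 1
        # never enters the conditional likelihood)
        self.p_occ = np.array(
            [t for t in range(1, self.T) if self.sampled[t]], dtype=int
        )
        self.n_p = 1 if spec.p_structure == "constant" else len(self.p_occ)
        self.n_par = self.n_phi + self.n_p
        self.hierarchical = (
            pooling and spec.phi_structure in ("constant", "temperature", "precipitation")
            and S >= 2
        )
        self.has_beta = spec.is_climate

    def phi_p(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map the (S, n_par) unconstrained block to (phi, p) probabilities."""
        S = theta.shape[0]
        if self.spec.phi_structure == "constant":
            phi = np.repeat(expit(theta[:, :1]), self.T - 1, axis=1)
        elif self.spec.is_climate:
            phi = expit(theta[:, :1] + theta[:, 1:2] * self.x[None, :])
        else:
            phi = expit(theta[:, : self.n_phi])
        p = np.zeros((S, self.T))
        block = theta[:, self.n_phi :]
        if self.spec.p_structure == "constant":
            vals = expit(block[:, 0])
            p[:, self.p_occ] = vals[:, None]
        else:
            p[:, self.p_occ] = expit(block)
        return phi, p

    def coord_kind(self, j: int) -> str:
        if self.spec.phi_structure in ("constant",) and j == 0:
            return "alpha"
        if self.spec.is_climate:
            if j == 0:
                return "alpha"
            if j == 1:
                return "beta"
        if j < self.n_phi:
            return "unit"  # free time-varying logit-phi, Uniform(0,1) prior
        return "unit"  # logit-p coordinates, Uniform(0,1) prior


def _unit_logprior(u: np.ndarray) -> np.ndarray:
    # Uniform(0,1) on the probability scale plus the logit Jacobian
    return log_expit(u) + log_expit(-u)


def _normal_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


@dataclass
class PosteriorDraws:
    """Labelled posterior draws plus pointwise log-likelihood components.

    ``params`` arrays are shaped (chain, draw, ...); species-level arrays
    have the species axis last, ordered as ``species``. For hierarchical
    fits the stored deviations satisfy
    ``alpha = mu_alpha + sigma_alpha * z_alpha`` exactly (same for beta).
    """

    spec: ModelSpec
    species: list
    params: dict[str, np.ndarray]
    pointwise: np.ndarray  # (chain, draw, n_individuals)
    individuals: np.ndarray
    species_of_individual: np.ndarray
    calendar: OccasionCalendar
    climate: ClimateSeries | None
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.pointwise.shape[0]

    @property
    def n_draws(self) -> int:
        return self.pointwise.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def species_index(self, species) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def phi_draws(self, species) -> np.ndarray:
        """Per-interval survival, shape (n_total_draws, T-1)."""
        s = self.species_index(species)
        T = self.calendar.n_occasions
        if self.spec.phi_structure == "constant":
            a = self.flat("alpha")[:, s]
            return np.repeat(expit(a)[:, None], T - 1, axis=1)
        if self.spec.is_climate:
            a = self.flat("alpha")[:, s]
            b = self.flat("beta")[:, s]
            x = interval_covariate(self.spec, self.climate, self.calendar)
            return expit(a[:, None] + b[:, None] * x[None, :])
        return expit(self.flat("logit_phi")[:, s, :])

    def p_draws(self, species) -> np.ndarray:
        s = self.species_index(species)
        T = self.calendar.n_occasions
        p_occ = self.params["_p_occ"]
        out = np.zeros((self.n_chains * self.n_draws, T))
        if self.spec.p_structure == "constant":
            out[:, p_occ] = expit(self.flat("logit_p")[:, s])[:, None]
        else:
            out[:, p_occ] = expit(self.flat("logit_p")[:, s, :])
        return out

    def pointwise_flat(self) -> np.ndarray:
        return self.pointwise.reshape(-1, self.pointwise.shape[2])

    def total_loglik(self) -> np.ndarray:
        """Data log-likelihood per draw, flattened over chains."""
        return self.pointwise_flat().sum(axis=1)

    def species_loglik(self, species) -> np.ndarray:
        mask = self.species_of_individual == species
        return self.pointwise_flat()[:, mask].sum(axis=1)

    def to_inference_data(self):
        import arviz as az

        data = {}
        for name, arr in self.params.items():
            if name.startswith("_"):
                continue
            data[name] = arr
        coords = {"species": self.species}
        dims = {}
        for name, arr in data.items():
            if arr.ndim == 3 and arr.shape[2] == len(self.species):
                dims[name] = ["species"]
            elif arr.ndim == 4:
                dims[name] = ["species", f"{name}_dim"]
        return az.from_dict(posterior=data, coords=coords, dims=dims)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.params.items():
            if name.startswith("_"):
                continue
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            for k in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{k}]"
                q = np.percentile(flat[:, k], [2.5, 50, 97.5])
                rows.append((label, flat[:, k].mean(), q[0], q[1], q[2]))
        return pd.DataFrame(rows, columns=["parameter", "mean", "q2.5", "median", "q97.5"])


def log_posterior(
    state: Mapping[str, np.ndarray],
    matrix: CaptureHistoryMatrix,
    spec: ModelSpec,
    climate: ClimateSeries | None = None,
    pooling: bool = True,
    prior_scheme: Literal["improper", "weak"] = "improper",
) -> float:
    """Joint log density (likelihood + priors) at a constrained-scale state.

    ``state`` holds probability-scale detection (``p``: per species, or per
    species x sampled-occasion) and survival parameters on their natural
    scales (``alpha``/``beta`` logit-scale per species, or ``phi_time``
    probability-scale per species x interval), plus the hyperparameters for
    hierarchical fits. Out-of-support states return ``-inf``.
    """
    comm = CommunityLikelihood(matrix)
    layout = _Layout(spec, matrix.calendar, climate, comm.S, pooling)
    T = comm.T

    p_vals = np.atleast_1d(np.asarray(state["p"], dtype=float))
    if np.any((p_vals < 0) | (p_vals > 1)):
        return -np.inf
    p = np.zeros((comm.S, T))
    if spec.p_structure == "constant":
        p[:, layout.p_occ] = p_vals.reshape(comm.S, 1)
    else:
        p[:, layout.p_occ] = p_vals.reshape(comm.S, len(layout.p_occ))

    logprior = 0.0
    if spec.phi_structure == "time":
        phi = np.asarray(state["phi_time"], dtype=float).reshape(comm.S, T - 1)
        if np.any((phi < 0) | (phi > 1)):
            return -np.inf
    else:
        alpha = np.asarray(state["alpha"], dtype=float).reshape(comm.S)
        if spec.is_climate:
            beta = np.asarray(state["beta"], dtype=float).reshape(comm.S)
            phi = expit(alpha[:, None] + beta[:, None] * layout.x[None, :])
        else:
            phi = np.repeat(expit(alpha)[:, None], T - 1, axis=1)
        if layout.hierarchical:
            mu_a, sig_a = float(state["mu_alpha"]), float(state["sigma_alpha"])
            if sig_a <= 0:
                return -np.inf
            logprior += _normal_logpdf(alpha, mu_a, sig_a).sum()
            if prior_scheme == "weak":
                logprior += _normal_logpdf(mu_a, 0.0, 10.0)
                logprior += _normal_logpdf(sig_a, 0.0, 5.0) + np.log(2.0)
            if spec.is_climate:
                mu_b, sig_b = float(state["mu_beta"]), float(state["sigma_beta"])
                if sig_b <= 0:
                    return -np.inf
                logprior += _normal_logpdf(beta, mu_b, sig_b).sum()
                if prior_scheme == "weak":
                    logprior += _normal_logpdf(mu_b, 0.0, 10.0)
                    logprior += _normal_logpdf(sig_b, 0.0, 5.0) + np.log(2.0)
    # uniform priors on p (and on free time-varying phi) contribute 0
    ll = comm.loglik_all(phi, p).sum()
    return float(ll + logprior)


def sample_posterior(
    matrix: CaptureHistoryMatrix,
    spec: ModelSpec,
    climate: ClimateSeries | None = None,
    *,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int,
    pooling: bool = True,
    prior_scheme: Literal["improper", "weak"] = "improper",
    compute_pointwise: bool = True,
) -> PosteriorDraws:
    """Draw from the posterior of a candidate CJS model.

    Deterministic given ``seed`` and configuration. Chains are run
    sequentially from independent, over-dispersed random initializations.
    """
    comm = CommunityLikelihood(matrix)
    layout = _Layout(spec, matrix.calendar, climate, comm.S, pooling)
    S, T, n_par = comm.S, comm.T, layout.n_par
    rng_chains = [
        np.random.Generator(np.random.PCG64(ss))
        for ss in np.random.SeedSequence(seed).spawn(chains)
    ]

    def run_chain(rng) -> dict[str, np.ndarray]:
        theta = np.zeros((S, n_par))
        theta[:, : layout.n_phi] = rng.normal(0.3, 0.6, size=(S, layout.n_phi))
        if layout.has_beta:
            theta[:, 1] = rng.normal(0.0, 0.3, size=S)
        theta[:, layout.n_phi :] = rng.normal(-0.4, 0.6, size=(S, layout.n_p))
        hyp = {
            "mu_alpha": float(theta[:, 0].mean()),
            "sigma_alpha": float(theta[:, 0].std() + 0.2),
            "mu_beta": float(theta[:, 1].mean()) if layout.has_beta else 0.0,
            "sigma_beta": (
                float(theta[:, 1].std() + 0.2) if layout.has_beta else 1.0
            ),
        }
        log_steps = np.full((S, n_par), np.log(0.4))
        phi, p = layout.phi_p(theta)
        cur_ll = comm.loglik_all(phi, p)

        def coord_logprior(j, col):
            kind = layout.coord_kind(j)
            if kind == "alpha" and layout.hierarchical:
                return _normal_logpdf(col, hyp["mu_alpha"], hyp["sigma_alpha"])
            if kind == "beta" and layout.hierarchical:
                return _normal_logpdf(col, hyp["mu_beta"], hyp["sigma_beta"])
            if kind in ("alpha", "beta"):
                return np.zeros_like(col)  # flat when pooling is off
            return _unit_logprior(col)

        def gibbs_hypers():
            # exact conjugate refresh under flat (improper) hyperpriors
            cols = [("alpha", 0)] + ([("beta", 1)] if layout.has_beta else [])
            for name, j in cols:
                vals = theta[:, j]
                sig = hyp[f"sigma_{name}"]
                hyp[f"mu_{name}"] = float(
                    rng.normal(vals.mean(), sig / np.sqrt(S))
                )
                A = float(((vals - hyp[f"mu_{name}"]) ** 2).sum())
                var = (A / 2.0) / rng.gamma((S - 1) / 2.0)
                hyp[f"sigma_{name}"] = float(np.sqrt(var))

        def mh_hypers(step=0.15):
            # weakly-informative proper scheme: random-walk on the hypers
            cols = [("alpha", 0)] + ([("beta", 1)] if layout.has_beta else [])
            for name, j in cols:
                vals = theta[:, j]

                def dens(mu, sig):
                    if sig <= 0:
                        return -np.inf
                    return (
                        _normal_logpdf(vals, mu, sig).sum()
                        + _normal_logpdf(mu, 0.0, 10.0)
                        + _normal_logpdf(sig, 0.0, 5.0)
                    )

                mu, sig = hyp[f"mu_{name}"], hyp[f"sigma_{name}"]
                for _ in range(2):
                    mu_p = mu + step * rng.standard_normal()
                    sig_p = sig + step * rng.standard_normal()
                    if np.log(rng.random()) < dens(mu_p, sig_p) - dens(mu, sig):
                        mu, sig = mu_p, sig_p
                hyp[f"mu_{name}"], hyp[f"sigma_{name}"] = mu, sig

        n_keep = draws
        store_theta = np.empty((n_keep, S, n_par))
        store_hyp = np.empty((n_keep, 4))
        total = warmup + draws
        for it in range(total):
            for j in range(n_par):
                prop = theta.copy()
                prop[:, j] = theta[:, j] + np.exp(log_steps[:, j]) * rng.standard_normal(S)
                phi_p, p_p = layout.phi_p(prop)
                new_ll = comm.loglik_all(phi_p, p_p)
                delta = (
                    new_ll
                    - cur_ll
                    + coord_logprior(j, prop[:, j])
                    - coord_logprior(j, theta[:, j])
                )
                accept = np.log(rng.random(S)) < delta
                theta[accept, j] = prop[accept, j]
                cur_ll[accept] = new_ll[accept]
                if it < warmup:
                    rate = min(0.25, 5.0 / np.sqrt(it + 10.0))
                    log_steps[:, j] += rate * (accept.astype(float) - _TARGET_ACCEPT)
            if layout.hierarchical:
                if prior_scheme == "improper":
                    gibbs_hypers()
                else:
                    mh_hypers()
            if it >= warmup:
                k = it - warmup
                store_theta[k] = theta
                store_hyp[k] = (
                    hyp["mu_alpha"],
                    hyp["sigma_alpha"],
                    hyp["mu_beta"],
                    hyp["sigma_beta"],
                )
        return {"theta": store_theta, "hyp": store_hyp}

    chain_results = [run_chain(rng) for rng in rng_chains]
    theta_all = np.stack([c["theta"] for c in chain_results])  # (C, D, S, n_par)
    hyp_all = np.stack([c["hyp"] for c in chain_results])  # (C, D, 4)

    params: dict[str, np.ndarray] = {"_p_occ": layout.p_occ}
    if spec.phi_structure == "time":
        params["logit_phi"] = theta_all[..., : layout.n_phi]
    else:
        params["alpha"] = theta_all[..., 0]
        if layout.has_beta:
            params["beta"] = theta_all[..., 1]
    if spec.p_structure == "constant":
        params["logit_p"] = theta_all[..., layout.n_phi]
    else:
        params["logit_p"] = theta_all[..., layout.n_phi :]
    if layout.hierarchical:
        params["mu_alpha"] = hyp_all[..., 0]
        params["sigma_alpha"] = hyp_all[..., 1]
        params["z_alpha"] = (params["alpha"] - params["mu_alpha"][..., None]) / params[
            "sigma_alpha"
        ][..., None]
        if layout.has_beta:
            params["mu_beta"] = hyp_all[..., 2]
            params["sigma_beta"] = hyp_all[..., 3]
            params["z_beta"] = (params["beta"] - params["mu_beta"][..., None]) / params[
                "sigma_beta"
            ][..., None]

    # pointwise per-individual log-likelihood for LOO / ANODEV
    C, D = chains, draws
    if compute_pointwise:
        pointwise = np.empty((C * D, comm.n_individuals))
        theta_flat = theta_all.reshape(C * D, S, n_par)
        for s_idx, sl in enumerate(comm.per_species):
            th = theta_flat[:, s_idx, :]  # (K, n_par)
            phi_k, p_k = _species_phi_p(layout, th)
            pointwise[:, comm.rows[s_idx]] = sl.pointwise_loglik(phi_k, p_k)
        pointwise = pointwise.reshape(C, D, comm.n_individuals)
    else:
        pointwise = np.zeros((C, D, 0))

    matrix_species = matrix.species
    fit = PosteriorDraws(
        spec=spec,
        species=comm.species,
        params=params,
        pointwise=pointwise,
        individuals=matrix.individuals,
        species_of_individual=matrix_species,
        calendar=matrix.calendar,
        climate=climate,
        seed=seed,
        config={
            "chains": chains,
            "warmup": warmup,
            "draws": draws,
            "pooling": pooling,
            "prior_scheme": prior_scheme,
        },
    )
    return fit


def _species_phi_p(layout: _Layout, th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi (K, T-1) and p (K, T) for one species' stacked draws."""
    K = th.shape[0]
    T = layout.T
    if layout.spec.phi_structure == "constant":
        phi = np.repeat(expit(th[:, :1]), T - 1, axis=1)
    elif layout.spec.is_climate:
        phi = expit(th[:, :1] + th[:, 1:2] * layout.x[None, :])
    else:
        phi = expit(th[:, : layout.n_phi])
    p = np.zeros((K, T))
    block = th[:, layout.n_phi :]
    if layout.spec.p_structure == "constant":
        p[:, layout.p_occ] = expit(block[:, 0])[:, None]
    else:
        p[:, layout.p_occ] = expit(block)
    return phi, p


def derived_annual_survival(
    fit: PosteriorDraws, species, climate: ClimateSeries | None = None
) -> pd.DataFrame:
    """Posterior per-interval survival for one species under a climate model.

    Rows are survival intervals labelled by the year whose dry season drives
    them; columns give the posterior median and central 95% interval.
    """
    if not fit.spec.is_climate:
        raise ValueError("derived annual survival requires a climate-driven fit")
    climate = climate if climate is not None else fit.climate
    phi = fit.phi_draws(species)  # (K, T-1)
    offset = 0 if fit.spec.covariate_alignment == "start" else 1
    years = fit.calendar.occasion_years[offset : offset + fit.calendar.n_occasions - 1]
    med = np.median(phi, axis=0)
    lo, hi = np.percentile(phi, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"year": years, "median": med, "q2.5": lo, "q97.5": hi}
    )


def percent_reduction(phi_ref, phi_alt):
    """Percent reduction 100 * (phi_ref - phi_alt) / phi_ref.

    Vectorized over posterior draws; summaries should be taken on the
    per-draw values, never on rounded point estimates.
    """
    ref = np.asarray(phi_ref, dtype=float)
    alt = np.asarray(phi_alt, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference survival must be positive")
    out = 100.0 * (ref - alt) / ref
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ImpactResult:
    """Posterior percent change in community-mean survival for a raw shift."""

    percent: float  # posterior mean of the per-draw percent reduction
    ci95: tuple[float, float]
    draws: np.ndarray
    raw_shift: float
    z_shift: float


def community_climate_impact(
    fit: PosteriorDraws, raw_shift: float, series: ClimateSeries | None = None
) -> ImpactResult:
    """Percent change in community-mean survival for a raw covariate shift.

    Per draw, the baseline is the community-mean survival at the covariate
    mean (z = 0), ``phi0 = logistic(mu_alpha)``; the shifted value is
    ``phi1 = logistic(mu_alpha + mu_beta * z_shift)`` where ``z_shift``
    converts the raw shift (degrees C or mm) into standardized units. The
    summary is the posterior mean of the per-draw percent reduction.
    """
    if not fit.spec.is_climate:
        raise ValueError("community impact requires a climate-driven fit")
    if "mu_alpha" not in fit.params:
        raise ValueError("community impact requires a pooled (hierarchical) fit")
    series = series if series is not None else fit.climate
    if fit.spec.covariate == "temperature":
        z_shift = celsius_to_z(raw_shift, series)
    else:
        z_shift = mm_to_z(raw_shift, series)
    mu_a = fit.flat("mu_alpha")
    mu_b = fit.flat("mu_beta")
    phi0 = expit(mu_a)
    phi1 = expit(mu_a + mu_b * z_shift)
    per_draw = percent_reduction(phi0, phi1)
    lo, hi = np.percentile(per_draw, [2.5, 97.5])
    return ImpactResult(
        percent=float(per_draw.mean()),
        ci95=(float(lo), float(hi)),
        draws=per_draw,
        raw_shift=float(raw_shift),
        z_shift=float(z_shift),
    )


@dataclass(frozen=True)
class ConvergenceReport:
    passed: bool
    table: pd.DataFrame
    rhat_available: bool
    failures: pd.DataFrame


def convergence_check(
    fit: PosteriorDraws, rhat_max: float = 1.01, ess_min: float = 400.0
) -> ConvergenceReport:
    """Split-R-hat and bulk ESS per parameter against QC thresholds.

    With a single chain R-hat is unavailable; the report is explicitly
    partial (ESS only) in that case.
    """
    import arviz as az

    idata = fit.to_inference_data()
    ess = az.ess(idata)
    rhat_available = fit.n_chains >= 2
    rows = []
    rhat = az.rhat(idata) if rhat_available else None
    for name in ess.data_vars:
        e = np.atleast_1d(ess[name].values).ravel()
        r = (
            np.atleast_1d(rhat[name].values).ravel()
            if rhat is not None
            else np.full_like(e, np.nan)
        )
        for k, (ek, rk) in enumerate(zip(e, r)):
            label = name if e.size == 1 else f"{name}[{k}]"
            rows.append((label, rk, ek))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk"])
    bad_ess = table["ess_bulk"] < ess_min
    bad_rhat = (table["rhat"] > rhat_max) if rhat_available else pd.Series(
        False, index=table.index
    )
    failures = table[bad_ess | bad_rhat]
    passed = failures.empty and rhat_available
    if not failures.empty:
        logger.warning("convergence failures:\n%s", failures.to_string(index=False))
    return ConvergenceReport(
        passed=passed, table=table, rhat_available=rhat_available, failures=failures
    )
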