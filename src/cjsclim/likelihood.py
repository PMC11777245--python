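"""Exact marginalized Cormack-Jolly-Seber likelihood.

The CJS model conditions each encounter history on the occasion of first
capture and marginalizes the latent alive/dead process analytically via the
chi recursion: ``chi_t``, the probability an individual alive at occasion
``t`` is never detected again, satisfies

    chi_T = 1
    chi_t = (1 - phi_t) + phi_t * (1 - p_{t+1}) * chi_{t+1}

so the likelihood of a history with first detection ``f`` and last
detection ``l`` is the product of survival and detection/non-detection
factors over occasions ``f+1 .. l`` times ``chi_l``. All computation is in
log space; occasions without sampling have detection fixed to zero and
contribute factors of one.

Per-species sufficient statistics (how many individuals traverse each
interval, are detected / not detected at each occasion between their first
and last captures, and end at each occasion) make one likelihood evaluation
O(T) regardless of the number of individuals, which is what makes the MCMC
in :mod:`cjsclim.inference` cheap at community scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .capture import CaptureHistoryMatrix, OccasionCalendar
from .climate import ClimateSeries

__all__ = [
    "ModelSpec",
    "CJSParameters",
    "SpeciesLikelihood",
    "candidate_models",
    "chi_recursion",
    "log_chi_recursion",
    "history_loglik",
    "dataset_loglik",
    "build_phi",
]

PhiStructure = Literal["constant", "time", "temperature", "precipitation"]
PStructure = Literal["constant", "time"]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class ModelSpec:
    """One candidate CJS parameterization.

    ``covariate_alignment`` fixes which year's dry-season covariate drives
    survival over the interval (year t -> year t+1): ``"start"`` (default)
    uses year t — the dry season the bird must survive — ``"end"`` uses
    year t+1.
    """

    phi_structure: PhiStructure = "constant"
    p_structure: PStructure = "constant"
    covariate_alignment: Literal["start", "end"] = "start"

    @property
    def is_climate(self) -> bool:
        return self.phi_structure in ("temperature", "precipitation")

    @property
    def covariate(self) -> str | None:
        return self.phi_structure if self.is_climate else None

    @property
    def name(self) -> str:
        phi = {
            "constant": ".",
            "time": "t",
            "temperature": "temp",
            "precipitation": "precip",
        }[self.phi_structure]
        p = {"constant": ".", "time": "t"}[self.p_structure]
        return f"phi({phi})p({p})"

    @property
    def complexity(self) -> int:
        """Rough parameter-count ordering used for tie-breaking."""
        return {"constant": 0, "temperature": 1, "precipitation": 1, "time": 2}[
            self.phi_structure
        ] + {"constant": 0, "time": 2}[self.p_structure]


def candidate_models() -> list[ModelSpec]:
    """The full candidate set: every combination of time-dependent and
    time-independent detection and survival, plus temperature- and
    precipitation-driven survival with either detection structure."""
    specs = []
    for phi in ("constant", "time", "temperature", "precipitation"):
        for p in ("constant", "time"):
            specs.append(ModelSpec(phi_structure=phi, p_structure=p))
    return specs


@dataclass(frozen=True)
class CJSParameters:
    """Survival and detection probabilities for one species.

    ``phi`` has one entry per interval (length T-1), ``p`` one per occasion
    (length T, exactly 0 on unsampled occasions). For climate models the
    logit-scale intercept ``alpha`` and slope ``beta`` that generated
    ``phi`` are carried alongside.
    """

    phi: np.ndarray
    p: np.ndarray
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if len(p) != len(phi) + 1:
            raise ValueError("p must have one more entry than phi")
        for name, arr in (("phi", phi), ("p", p)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "p", p)


def _check_probs(phi: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(p) != len(phi) + 1:
        raise ValueError("len(p) must equal len(phi) + 1")
    if np.any((phi < 0) | (phi > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return phi, p


def log_chi_recursion(phi: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log chi_t for t = 1..T (returned 0-indexed, length T).

    Vectorized over an optional leading draw axis: ``phi`` may be (K, T-1)
    and ``p`` (K, T), giving a (K, T) result.
    """
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    one_dim = phi.ndim == 1
    phi = np.atleast_2d(phi)
    p = np.atleast_2d(p)
    K, Tm1 = phi.shape
    T = Tm1 + 1
    out = np.zeros((K, T))
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log_1mphi = np.log1p(-phi)
        log_1mp = np.log1p(-p)
    for t in range(T - 2, -1, -1):
        out[:, t] = np.logaddexp(
            log_1mphi[:, t], log_phi[:, t] + log_1mp[:, t + 1] + out[:, t + 1]
        )
    return out[0] if one_dim else out


def chi_recursion(phi: Sequence[float], p: Sequence[float]) -> np.ndarray:
    """chi_t on the probability scale (length T; ``chi_{T} = 1``)."""
    phi, p = _check_probs(np.asarray(phi), np.asarray(p))
    logchi = log_chi_recursion(phi[None, :], p[None, :])
    return np.exp(logchi[0])


def history_loglik(
    history: Sequence[int],
    first_capture: int,
    phi: Sequence[float],
    p: Sequence[float],
) -> float:
    """Log-probability of one encounter history, conditioned on first capture.

    ``first_capture`` is the 0-based occasion index of the first detection;
    occasions before it contribute nothing. A detection at an occasion with
    ``p = 0`` is impossible and raises.
    """
    y = np.asarray(history, dtype=int)
    phi, p = _check_probs(np.asarray(phi), np.asarray(p))
    if y.sum() == 0:
        raise ValueError("history has no detections; CJS conditions on first capture")
    f = int(first_capture)
    if y[f] != 1 or y[:f].any():
        raise ValueError("first_capture does not match the first 1 in the history")
    detected = np.flatnonzero(y)
    if np.any(p[detected[1:]] == 0):
        raise ValueError("detection recorded at an occasion with p = 0")
    l = int(detected[-1])
    logchi = log_chi_recursion(phi[None, :], p[None, :])[0]
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log_p = np.log(p)
        log_1mp = np.log1p(-p)
    total = logchi[l]
    for t in range(f, l):
        total += log_phi[t]
        total += log_p[t + 1] if y[t + 1] else log_1mp[t + 1]
    return float(total)


class SpeciesLikelihood:
    """Compiled encounter histories for one species.

    Precomputes sufficient statistics so the dataset log-likelihood is a
    dot product against per-interval/per-occasion log terms, plus 0/1
    membership matrices for per-individual (pointwise) log-likelihoods over
    posterior draws.
    """

    def __init__(self, detections: np.ndarray, sampled: np.ndarray):
        det = np.asarray(detections, dtype=np.int8)
        self.n, self.T = det.shape
        self.sampled = np.asarray(sampled, dtype=bool)
        first = np.argmax(det == 1, axis=1)
        last = self.T - 1 - np.argmax(det[:, ::-1] == 1, axis=1)
        self.first = first
        self.last = last
        t_idx = np.arange(self.T)
        in_window = (first[:, None] < t_idx[None, :]) & (t_idx[None, :] <= last[:, None])
        self.M_det = (in_window & (det == 1)).astype(float)  # (n, T)
        self.M_non = (in_window & (det == 0)).astype(float)
        ti = np.arange(self.T - 1)
        self.M_phi = (
            (first[:, None] <= ti[None, :]) & (ti[None, :] < last[:, None])
        ).astype(float)  # (n, T-1)
        # sufficient statistics
        self.A = self.M_phi.sum(axis=0)  # traversed intervals
        self.D = self.M_det.sum(axis=0)  # detections after first capture
        self.N = self.M_non.sum(axis=0)  # non-detections inside the window
        self.C = np.bincount(last, minlength=self.T).astype(float)
        if det.shape[0] and self.M_det[:, ~self.sampled].any():
            raise ValueError("detections present in unsampled occasions")

    @classmethod
    def from_matrix(cls, matrix: CaptureHistoryMatrix) -> "SpeciesLikelihood":
        return cls(matrix.detections, matrix.calendar.sampled)

    def _log_terms(self, phi: np.ndarray, p: np.ndarray):
        with np.errstate(divide="ignore"):
            log_phi = np.log(phi)
            log_p = np.log(p)
            log_1mp = np.log1p(-p)
        return log_phi, log_p, log_1mp

    def loglik(self, phi: np.ndarray, p: np.ndarray) -> float:
        """Total log-likelihood, O(T) via sufficient statistics."""
        phi, p = _check_probs(phi, p)
        log_phi, log_p, log_1mp = self._log_terms(phi, p)
        logchi = log_chi_recursion(phi[None, :], p[None, :])[0]
        def dot(w, lg):
            mask = w > 0
            if np.any(np.isneginf(lg[mask])):
                return -np.inf
            return float(w[mask] @ lg[mask])
        return (
            dot(self.A, log_phi)
            + dot(self.D, log_p)
            + dot(self.N, log_1mp)
            + dot(self.C, logchi)
        )

    def pointwise_loglik(self, phi_draws: np.ndarray, p_draws: np.ndarray) -> np.ndarray:
        """Per-individual log-likelihood for a stack of (K) parameter draws.

        Returns an array of shape (K, n_individuals).
        """
        phi_draws = np.atleast_2d(phi_draws)
        p_draws = np.atleast_2d(p_draws)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_phi = np.log(phi_draws)
            log_p = np.where(p_draws > 0, np.log(np.where(p_draws > 0, p_draws, 1.0)), 0.0)
            log_1mp = np.log1p(-p_draws)
        # keep -inf out of the matmuls (0 * -inf would poison rows that do
        # not even use the offending term); a counted term still dominates
        big_neg = -1e308
        log_phi = np.maximum(log_phi, big_neg)
        log_1mp = np.maximum(log_1mp, big_neg)
        logchi = log_chi_recursion(phi_draws, p_draws)  # (K, T)
        ll = (
            log_phi @ self.M_phi.T
            + log_p @ self.M_det.T
            + log_1mp @ self.M_non.T
            + logchi[:, self.last]
        )
        return ll


def build_phi(
    spec: ModelSpec,
    alpha: float | np.ndarray,
    beta: float | None,
    climate: ClimateSeries | None,
    calendar: OccasionCalendar,
) -> np.ndarray:
    """Per-interval survival vector implied by a model spec.

    constant: phi_t = logistic(alpha) for every interval; time: ``alpha``
    is the full logit-scale vector of free per-interval parameters;
    climate: phi_t = logistic(alpha + beta * x_t) with x_t the standardized
    covariate of the interval's aligned year.
    """
    T = calendar.n_occasions
    if spec.phi_structure == "constant":
        return np.full(T - 1, _expit(float(alpha)))
    if spec.phi_structure == "time":
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (T - 1,):
            raise ValueError(f"time model needs {T - 1} logit-phi values")
        return _expit(alpha)
    if climate is None:
        raise ValueError("climate model requires a standardized climate series")
    x = interval_covariate(spec, climate, calendar)
    return _expit(float(alpha) + float(beta) * x)


def interval_covariate(
    spec: ModelSpec, climate: ClimateSeries, calendar: OccasionCalendar
) -> np.ndarray:
    """Standardized covariate value aligned to each survival interval."""
    offset = 0 if spec.covariate_alignment == "start" else 1
    years = calendar.occasion_years[offset : offset + calendar.n_occasions - 1]
    missing = set(years.tolist()) - set(climate.years.tolist())
    if missing:
        raise ValueError(f"climate series missing interval years: {sorted(missing)}")
    which = "temperature" if spec.phi_structure == "temperature" else "precipitation"
    col = climate.covariate(which, z=True)
    lookup = {int(y): col[i] for i, y in enumerate(climate.years)}
    return np.array([lookup[int(y)] for y in years])


def dataset_loglik(
    matrix: CaptureHistoryMatrix,
    params: Mapping[object, CJSParameters],
) -> tuple[float, np.ndarray]:
    """Total and per-individual log-likelihood under per-species parameters.

    The per-individual vector is aligned to the matrix row order; it is the
    pointwise unit consumed by leave-one-out cross-validation.
    """
    missing = set(matrix.species_list()) - set(params.keys())
    if missing:
        raise ValueError(f"species missing parameters: {sorted(map(str, missing))}")
    out = np.zeros(matrix.n_individuals)
    for sp in matrix.species_list():
        rows = np.flatnonzero(matrix.species == sp)
        sub = SpeciesLikelihood(matrix.detections[rows], matrix.calendar.sampled)
        pr = params[sp]
        ll = sub.pointwise_loglik(pr.phi[None, :], pr.p[None, :])[0]
        out[rows] = ll
    return float(out.sum()), out
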