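"""Annual dry-season climate covariates for survival modelling.

The survival models downstream regress logit-survival on standardized
(z-transformed) dry-season temperature and precipitation. This module holds
the yearly covariate table, its standardization, and the small summary
statistics reported alongside the survival analysis: the temperature trend,
the temperature-precipitation collinearity, and the identification of extreme
(coolest/hottest, wettest/driest) years.

Raster reanalysis handling is out of scope: the input is a yearly table
``year, temp_c, precip_mm`` (or sub-annual records reduced by
:func:`aggregate_dry_season`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ClimateSeries",
    "DEFAULT_DRY_SEASON_MONTHS",
    "read_climate_csv",
    "aggregate_dry_season",
    "zscore_covariates",
    "climate_correlation",
    "climate_trend",
    "identify_extreme_years",
    "celsius_to_z",
    "mm_to_z",
]

#: June-November, the dry season at the central-Amazon study region.
DEFAULT_DRY_SEASON_MONTHS: tuple[int, ...] = (6, 7, 8, 9, 10, 11)

Covariate = Literal["temperature", "precipitation"]


class DegenerateCovariateError(ValueError):
    """Raised when a covariate has zero variance where variance is required."""


@dataclass(frozen=True)
class ClimateSeries:
    """Per-year dry-season climate covariates, raw and standardized.

    Parameters
    ----------
    years
        Strictly increasing calendar years.
    temp_c
        Mean dry-season temperature per year (degrees C).
    precip_mm
        Dry-season precipitation per year (mm).
    temp_z, precip_z
        z-transformed covariates; ``None`` until :func:`zscore_covariates`
        has been applied.
    reference_years
        Years over which the standardization constants were computed.
    """

    years: np.ndarray
    temp_c: np.ndarray
    precip_mm: np.ndarray
    temp_z: np.ndarray | None = None
    precip_z: np.ndarray | None = None
    reference_years: tuple[int, ...] | None = None
    # standardization constants, kept so raw-scale shifts can be mapped to
    # model (z) units and so the transform is invertible
    temp_mean: float | None = field(default=None, compare=False)
    temp_sd: float | None = field(default=None, compare=False)
    precip_mean: float | None = field(default=None, compare=False)
    precip_sd: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        temp = np.asarray(self.temp_c, dtype=float)
        precip = np.asarray(self.precip_mm, dtype=float)
        if not (len(years) == len(temp) == len(precip)):
            raise ValueError("years, temp_c and precip_mm must have equal length")
        if len(years) == 0:
            raise ValueError("climate series must contain at least one year")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing with no duplicates")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "temp_c", temp)
        object.__setattr__(self, "precip_mm", precip)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def standardized(self) -> bool:
        return self.temp_z is not None

    def covariate(self, which: Covariate, *, z: bool = True) -> np.ndarray:
        """Return the requested covariate column (z-scored by default)."""
        if which == "temperature":
            col = self.temp_z if z else self.temp_c
        elif which == "precipitation":
            col = self.precip_z if z else self.precip_mm
        else:
            raise ValueError(f"unknown covariate {which!r}")
        if col is None:
            raise ValueError(
                "series is not standardized; call zscore_covariates first"
            )
        return col

    def value_for_year(self, year: int, which: Covariate, *, z: bool = True) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in climate series")
        return float(self.covariate(which, z=z)[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "temp_c": self.temp_c, "precip_mm": self.precip_mm}
        if self.standardized:
            data["temp_z"] = self.temp_z
            data["precip_z"] = self.precip_z
        return pd.DataFrame(data)


def read_climate_csv(path) -> ClimateSeries:
    """Read a yearly climate table with strict header ``year,temp_c,precip_mm``."""
    df = pd.read_csv(path)
    required = ["year", "temp_c", "precip_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"climate CSV missing required columns: {missing}")
    for col in required:
        if df[col].isna().any():
            raise ValueError(f"climate CSV column {col!r} contains missing values")
    years = df["year"].to_numpy()
    if not np.array_equal(years, years.astype(int)):
        raise ValueError("climate CSV 'year' column must be integer-valued")
    order = np.argsort(years)
    df = df.iloc[order]
    return ClimateSeries(
        years=df["year"].to_numpy(dtype=int),
        temp_c=df["temp_c"].to_numpy(dtype=float),
        precip_mm=df["precip_mm"].to_numpy(dtype=float),
    )


def aggregate_dry_season(
    records: pd.DataFrame,
    months: Sequence[int] = DEFAULT_DRY_SEASON_MONTHS,
) -> ClimateSeries:
    """Reduce sub-annual records to a yearly dry-season series.

    ``records`` must have columns ``date`` (parseable), ``temp_c`` and
    ``precip_mm`` (daily mean temperature and daily total precipitation).
    Within each calendar year the dry-season days are averaged:
    mean of daily mean temperatures and mean of daily precipitation totals.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df[df["date"].dt.month.isin(list(months))]
    if df.empty:
        raise ValueError("no records fall inside the dry-season months")
    grouped = df.groupby(df["date"].dt.year)[["temp_c", "precip_mm"]].mean()
    return ClimateSeries(
        years=grouped.index.to_numpy(dtype=int),
        temp_c=grouped["temp_c"].to_numpy(),
        precip_mm=grouped["precip_mm"].to_numpy(),
    )


def _reference_mask(series: ClimateSeries, reference_years: Iterable[int] | None) -> np.ndarray:
    if reference_years is None:
        return np.ones(len(series), dtype=bool)
    ref = set(int(y) for y in reference_years)
    missing = ref - set(series.years.tolist())
    if missing:
        raise ValueError(f"reference years not present in series: {sorted(missing)}")
    return np.isin(series.years, sorted(ref))


def zscore_covariates(
    series: ClimateSeries, reference_years: Iterable[int] | None = None
) -> ClimateSeries:
    """Standardize both covariates to zero mean / unit sd over reference years.

    The mean and sample standard deviation (denominator ``n - 1``) are
    computed over ``reference_years`` only (default: all years); values
    outside the reference window are standardized with the same constants so
    the transform is a single affine map per covariate.
    """
    mask = _reference_mask(series, reference_years)
    if mask.sum() < 2:
        raise ValueError("need at least 2 reference years to standardize")

    def _constants(x: np.ndarray, name: str) -> tuple[float, float]:
        mean = float(np.mean(x[mask]))
        sd = float(np.std(x[mask], ddof=1))
        if sd == 0.0:
            raise DegenerateCovariateError(
                f"{name} has zero variance over the reference years"
            )
        return mean, sd

    t_mean, t_sd = _constants(series.temp_c, "temperature")
    p_mean, p_sd = _constants(series.precip_mm, "precipitation")
    ref = tuple(int(y) for y in series.years[mask])
    return replace(
        series,
        temp_z=(series.temp_c - t_mean) / t_sd,
        precip_z=(series.precip_mm - p_mean) / p_sd,
        reference_years=ref,
        temp_mean=t_mean,
        temp_sd=t_sd,
        precip_mean=p_mean,
        precip_sd=p_sd,
    )


def climate_correlation(series: ClimateSeries) -> float:
    """Pearson correlation between dry-season temperature and precipitation."""
    if len(series) < 3:
        raise ValueError("need at least 3 years to estimate a correlation")
    if np.std(series.temp_c) == 0 or np.std(series.precip_mm) == 0:
        raise DegenerateCovariateError("zero-variance covariate in correlation")
    return float(np.corrcoef(series.temp_c, series.precip_mm)[0, 1])


@dataclass(frozen=True)
class TrendFit:
    slope: float  # covariate units per calendar year
    intercept: float
    slope_se: float


def climate_trend(series: ClimateSeries, covariate: Covariate) -> TrendFit:
    """OLS trend of a covariate against calendar year (units per year)."""
    if len(series) < 3:
        raise ValueError("need at least 3 years to fit a trend")
    y = series.covariate(covariate, z=False)
    X = sm.add_constant(series.years.astype(float))
    fit = sm.OLS(y, X).fit()
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
    )


def identify_extreme_years(
    series: ClimateSeries, covariate: Covariate
) -> tuple[int, int]:
    """Return (year of minimum, year of maximum) of a covariate.

    For temperature this is (coolest, hottest); for precipitation
    (driest, wettest) in value order — i.e. always (argmin, argmax).
    Ties are broken toward the earliest year.
    """
    x = series.covariate(covariate, z=False)
    return int(series.years[int(np.argmin(x))]), int(series.years[int(np.argmax(x))])


def _raw_to_z(delta: float, sd: float | None, name: str) -> float:
    if sd is None:
        raise ValueError("series is not standardized; call zscore_covariates first")
    if sd == 0:
        raise DegenerateCovariateError(f"{name} sd is zero")
    return float(delta) / sd


def celsius_to_z(delta_c: float, series: ClimateSeries) -> float:
    """Convert a raw temperature shift (degrees C) to standardized units."""
    return _raw_to_z(delta_c, series.temp_sd, "temperature")


def mm_to_z(delta_mm: float, series: ClimateSeries) -> float:
    """Convert a raw precipitation shift (mm) to standardized units."""
    return _raw_to_z(delta_mm, series.precip_sd, "precipitation")
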