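"""Individual encounter histories over annual capture occasions.

Mark-recapture data enter the survival models as one binary detection vector
per banded individual, aligned to an :class:`OccasionCalendar` of annual
occasions, some of which may be unsampled (no netting that year; downstream
models fix detection to zero there). Readers are provided for a long CSV
dialect and for MARK-style ``.inp`` encounter-history records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "OccasionCalendar",
    "CaptureHistoryMatrix",
    "read_encounter_histories",
    "write_encounter_histories",
    "read_calendar_csv",
    "collapse_to_annual",
    "filter_individuals",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An encounter-history matrix violates a structural invariant."""


@dataclass(frozen=True)
class OccasionCalendar:
    """Annual capture occasions with a sampled/unsampled flag per year."""

    occasion_years: np.ndarray
    sampled: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.occasion_years, dtype=int)
        sampled = np.asarray(self.sampled, dtype=bool)
        if len(years) != len(sampled):
            raise ValueError("occasion_years and sampled must have equal length")
        if len(years) < 2:
            raise ValueError("calendar needs at least 2 occasions")
        if np.any(np.diff(years) <= 0):
            raise ValueError("occasion years must be strictly increasing")
        if not sampled[0]:
            raise ValueError("first occasion must be sampled")
        if not sampled[-1]:
            # Trailing unsampled years carry no information for conditional
            # CJS likelihoods; permitted but flagged.
            logger.warning("last occasion is unsampled; it adds no information")
        object.__setattr__(self, "occasion_years", years)
        object.__setattr__(self, "sampled", sampled)

    @classmethod
    def all_sampled(cls, years: Iterable[int]) -> "OccasionCalendar":
        years = np.asarray(list(years), dtype=int)
        return cls(years, np.ones(len(years), dtype=bool))

    @classmethod
    def with_unsampled(
        cls, years: Iterable[int], unsampled: Iterable[int]
    ) -> "OccasionCalendar":
        years = np.asarray(list(years), dtype=int)
        sampled = ~np.isin(years, list(unsampled))
        return cls(years, sampled)

    def __len__(self) -> int:
        return len(self.occasion_years)

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_years)

    def index_of_year(self, year: int) -> int:
        idx = np.flatnonzero(self.occasion_years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not an occasion")
        return int(idx[0])


@dataclass(frozen=True)
class CaptureHistoryMatrix:
    """Binary detection matrix (individuals x occasions) with species labels.

    Rows are conditioned on first capture: every row has at least one
    detection, ``first_capture`` is the (0-based) occasion index of the
    first 1, and no detection may fall in an unsampled year.
    ``metadata`` optionally carries per-individual columns (age class,
    site, ...) used by :func:`filter_individuals`.
    """

    individuals: np.ndarray
    species: np.ndarray
    detections: np.ndarray
    calendar: OccasionCalendar
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        det = np.asarray(self.detections)
        if det.ndim != 2:
            raise ValidationError("detections must be a 2-D matrix")
        if not np.isin(det, (0, 1)).all():
            raise ValidationError("detections must be binary 0/1")
        det = det.astype(np.int8)
        ids = np.asarray(self.individuals)
        sp = np.asarray(self.species)
        if not (det.shape[0] == len(ids) == len(sp)):
            raise ValidationError("row count mismatch between ids, species, matrix")
        if det.shape[1] != self.calendar.n_occasions:
            raise ValidationError(
                f"matrix has {det.shape[1]} occasions, calendar has "
                f"{self.calendar.n_occasions}"
            )
        if len(ids) != len(set(ids.tolist())):
            dupes = pd.Series(ids).value_counts()
            raise ValidationError(
                f"duplicate individual ids: {dupes[dupes > 1].index.tolist()}"
            )
        if det.shape[0] > 0 and det.sum(axis=1).min() < 1:
            empty = ids[det.sum(axis=1) == 0]
            raise ValidationError(f"all-zero histories for individuals: {empty.tolist()}")
        bad = det[:, ~self.calendar.sampled]
        if bad.size and bad.any():
            rows = np.flatnonzero(det[:, ~self.calendar.sampled].any(axis=1))
            raise ValidationError(
                "detections in unsampled years for individuals: "
                f"{ids[rows].tolist()}"
            )
        if self.metadata is not None and len(self.metadata) != len(ids):
            raise ValidationError("metadata row count must match individuals")
        object.__setattr__(self, "individuals", ids)
        object.__setattr__(self, "species", sp)
        object.__setattr__(self, "detections", det)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[1]

    @property
    def first_capture(self) -> np.ndarray:
        """0-based occasion index of each individual's first detection."""
        return np.argmax(self.detections == 1, axis=1)

    @property
    def last_capture(self) -> np.ndarray:
        T = self.n_occasions
        return T - 1 - np.argmax(self.detections[:, ::-1] == 1, axis=1)

    def species_list(self) -> list:
        return sorted(set(self.species.tolist()))

    def captures_per_species(self) -> pd.Series:
        """Total detections (captures) per species."""
        df = pd.DataFrame(
            {"species": self.species, "captures": self.detections.sum(axis=1)}
        )
        return df.groupby("species")["captures"].sum()

    def individuals_per_species(self) -> pd.Series:
        return pd.Series(self.species).value_counts().sort_index()

    def subset(self, keep: np.ndarray) -> "CaptureHistoryMatrix":
        meta = self.metadata.iloc[keep].reset_index(drop=True) if self.metadata is not None else None
        return CaptureHistoryMatrix(
            individuals=self.individuals[keep],
            species=self.species[keep],
            detections=self.detections[keep],
            calendar=self.calendar,
            metadata=meta,
        )

    def for_species(self, species) -> "CaptureHistoryMatrix":
        keep = np.flatnonzero(self.species == species)
        if keep.size == 0:
            raise KeyError(f"no individuals of species {species!r}")
        return self.subset(keep)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.individuals):
            for t, year in enumerate(self.calendar.occasion_years):
                rows.append((ind, self.species[i], int(year), int(self.detections[i, t])))
        return pd.DataFrame(rows, columns=["individual", "species", "year", "detected"])


def read_calendar_csv(path) -> OccasionCalendar:
    """Read a calendar CSV with header ``year,sampled`` (sampled as 0/1)."""
    df = pd.read_csv(path)
    for col in ("year", "sampled"):
        if col not in df.columns:
            raise ValueError(f"calendar CSV missing column {col!r}")
    df = df.sort_values("year")
    return OccasionCalendar(
        df["year"].to_numpy(dtype=int), df["sampled"].astype(int).to_numpy().astype(bool)
    )


def _read_long_csv(path, calendar: OccasionCalendar) -> CaptureHistoryMatrix:
    df = pd.read_csv(path)
    required = ["individual", "species", "year", "detected"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"encounter CSV missing columns: {missing}")
    if not df["detected"].isin((0, 1)).all():
        raise ValueError("'detected' column must be binary 0/1")
    # conflicting duplicates
    g = df.groupby(["individual", "year"])["detected"].nunique()
    if (g > 1).any():
        offenders = g[g > 1].index.tolist()
        raise ValueError(f"conflicting duplicate (individual, year) records: {offenders}")
    df = df.drop_duplicates(["individual", "year"])
    sp_per_ind = df.groupby("individual")["species"].nunique()
    if (sp_per_ind > 1).any():
        raise ValidationError(
            "individual ids reused across species: "
            f"{sp_per_ind[sp_per_ind > 1].index.tolist()}"
        )
    unknown = set(df["year"]) - set(calendar.occasion_years.tolist())
    if unknown:
        raise ValueError(f"years outside calendar: {sorted(unknown)}")
    pivot = (
        df.pivot(index="individual", columns="year", values="detected")
        .reindex(columns=calendar.occasion_years, fill_value=0)
        .fillna(0)
        .astype(int)
    )
    species = df.drop_duplicates("individual").set_index("individual")["species"]
    species = species.reindex(pivot.index)
    return CaptureHistoryMatrix(
        individuals=pivot.index.to_numpy(),
        species=species.to_numpy(),
        detections=pivot.to_numpy(),
        calendar=calendar,
    )


_MARK_RECORD = re.compile(r"^([01]+)\s+(\S+)\s+(\d+)\s*;$")


def _read_mark_inp(path, calendar: OccasionCalendar) -> CaptureHistoryMatrix:
    text = Path(path).read_text()
    text = re.sub(r"/\*.*?\*/", " ", text, flags=re.S)  # strip comments
    rows, species, ids = [], [], []
    counter = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _MARK_RECORD.match(line)
        if m is None:
            raise ValueError(f"malformed MARK record: {line!r}")
        hist, group, count = m.groups()
        if len(hist) != calendar.n_occasions:
            raise ValueError(
                f"history length {len(hist)} does not match "
                f"{calendar.n_occasions} occasions: {line!r}"
            )
        vec = np.frombuffer(hist.encode(), dtype=np.uint8) - ord("0")
        for _ in range(int(count)):
            counter += 1
            ids.append(f"{group}_{counter:05d}")
            species.append(group)
            rows.append(vec)
    if not rows:
        raise ValueError("no records found in MARK input")
    return CaptureHistoryMatrix(
        individuals=np.array(ids),
        species=np.array(species),
        detections=np.vstack(rows),
        calendar=calendar,
    )


def read_encounter_histories(
    path, calendar: OccasionCalendar, dialect: Literal["csv", "mark_inp"] = "csv"
) -> CaptureHistoryMatrix:
    """Read encounter histories in long-CSV or MARK ``.inp`` dialect."""
    if dialect == "csv":
        return _read_long_csv(path, calendar)
    if dialect == "mark_inp":
        return _read_mark_inp(path, calendar)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_encounter_histories(
    matrix: CaptureHistoryMatrix, path, dialect: Literal["csv", "mark_inp"] = "csv"
) -> None:
    if dialect == "csv":
        matrix.to_long_frame().to_csv(path, index=False)
        return
    if dialect == "mark_inp":
        # collapse identical (species, history) rows to counted records
        lines = []
        df = pd.DataFrame(
            {
                "species": matrix.species,
                "hist": ["".join(map(str, row)) for row in matrix.detections],
            }
        )
        for (sp, hist), grp in df.groupby(["species", "hist"], sort=True):
            lines.append(f"{hist} {sp} {len(grp)};")
        Path(path).write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def collapse_to_annual(
    events: pd.DataFrame, calendar: OccasionCalendar
) -> CaptureHistoryMatrix:
    """Collapse within-year capture events to one annual detection.

    ``events`` must have columns ``individual``, ``species``, ``date``
    (parseable to a date). Any number of captures of an individual within an
    occasion year yields a single detection for that year.
    """
    df = events.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    unknown = set(df["year"]) - set(calendar.occasion_years.tolist())
    if unknown:
        raise ValueError(f"capture events outside calendar years: {sorted(unknown)}")
    long = (
        df.groupby(["individual", "species", "year"])
        .size()
        .reset_index(name="k")
        .assign(detected=1)[["individual", "species", "year", "detected"]]
    )
    sp_per_ind = long.groupby("individual")["species"].nunique()
    if (sp_per_ind > 1).any():
        raise ValidationError(
            "individual ids reused across species: "
            f"{sp_per_ind[sp_per_ind > 1].index.tolist()}"
        )
    pivot = (
        long.pivot(index="individual", columns="year", values="detected")
        .reindex(columns=calendar.occasion_years, fill_value=0)
        .fillna(0)
        .astype(int)
    )
    species = long.drop_duplicates("individual").set_index("individual")["species"]
    return CaptureHistoryMatrix(
        individuals=pivot.index.to_numpy(),
        species=species.reindex(pivot.index).to_numpy(),
        detections=pivot.to_numpy(),
        calendar=calendar,
    )


def filter_individuals(
    matrix: CaptureHistoryMatrix, exclude: Callable[[pd.Series], bool]
) -> CaptureHistoryMatrix:
    """Drop individuals matching an exclusion predicate on their metadata row.

    Typical use: removing known juveniles to limit transient bias. The
    predicate receives one metadata row (a Series including ``individual``
    and ``species``); a missing metadata column raises rather than silently
    keeping everything. Species left with zero individuals are dropped with
    a logged warning.
    """
    if matrix.metadata is not None:
        meta = matrix.metadata.copy()
    else:
        meta = pd.DataFrame(index=range(matrix.n_individuals))
    meta = meta.assign(individual=matrix.individuals, species=matrix.species)
    try:
        flags = meta.apply(lambda row: bool(exclude(row)), axis=1).to_numpy()
    except KeyError as exc:
        raise ValueError(f"exclusion predicate references missing metadata: {exc}") from exc
    keep = np.flatnonzero(~flags)
    before = set(matrix.species.tolist())
    out = matrix.subset(keep)
    lost = before - set(out.species.tolist())
    if lost:
        logger.warning("species removed entirely by filter: %s", sorted(lost))
    return out
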