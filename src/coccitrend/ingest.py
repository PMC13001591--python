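"""Trap-capture CSV ingestion, culling, and aggregation to analysis units.

The raw unit is one trap x week x species observation (a ``TrapRecord``).
Analysis operates on ``SampleAggregate`` units: total adult captures per
treatment x replicate x year for a taxon (a species, or one of the groups
``native``/``exotic``/``all``), together with the sampling effort — the
number of trap-weeks reporting data for that taxon in the same unit.

Records are carried as pandas DataFrames with the canonical column set
``RECORD_COLUMNS``; the dataclasses document the row schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .species import Origin, SpeciesRegistry

#: Canonical trap-record CSV header (one observation per row, UTF-8, comma-separated).
RECORD_COLUMNS = ["year", "day", "treatment", "replicate", "trap_id", "species", "adults"]

#: Canonical aggregate CSV header.
AGGREGATE_COLUMNS = ["treatment", "replicate", "year", "taxon_key", "captures", "effort"]

#: Group taxon keys emitted alongside per-species aggregates.
GROUP_KEYS = ("native", "exotic", "all")

#: Default culling rules: drop years before the survey's comparable period
#: and, within each year, observations after day-of-year 222 (August 10),
#: equalizing the sampling window across years.
CULL_FIRST_YEAR = 1993
CULL_LAST_DOY = 222


@dataclass(frozen=True)
class TrapRecord:
    """One trap x week x species observation."""

    year: int
    day: int  # day-of-year, 1..366
    treatment: str
    replicate: str
    trap_id: str
    species: str
    adults: int  # >= 0

    def __post_init__(self):
        if self.adults < 0:
            raise ValueError("adults must be >= 0")
        if not 1 <= self.day <= 366:
            raise ValueError("day-of-year must be in 1..366")


@dataclass(frozen=True)
class SampleAggregate:
    """Treatment x replicate x year totals for one taxon, with trap-week effort."""

    treatment: str
    replicate: str
    year: int
    taxon_key: str
    captures: int
    effort: int

    @property
    def captures_per_trap(self) -> float:
        if self.effort <= 0:
            raise ZeroDivisionError("captures_per_trap undefined at zero effort")
        return self.captures / self.effort


def _validate_records(df: pd.DataFrame, registry: SpeciesRegistry | None) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    # malformed numeric fields, reported with (1-based, header = line 1) line numbers
    for col in ("year", "day", "adults"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() | (coerced != np.floor(coerced))]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:10]]
            raise ValueError(f"non-integer values in column {col!r} at lines {lines}")
    if (df["adults"].astype(np.int64) < 0).any():
        bad = df.index[df["adults"].astype(np.int64) < 0]
        raise ValueError(f"negative adult counts at lines {[int(i) + 2 for i in bad[:10]]}")
    day = df["day"].astype(np.int64)
    if ((day < 1) | (day > 366)).any():
        bad = df.index[(day < 1) | (day > 366)]
        raise ValueError(f"day-of-year outside 1..366 at lines {[int(i) + 2 for i in bad[:10]]}")
    if registry is not None:
        labels = df["species"].unique()
        unknown = [lab for lab in labels if lab not in registry]
        if unknown:
            raise KeyError(f"species not in registry: {sorted(map(str, unknown))}")


def read_trap_csv(
    path: str | Path,
    registry: SpeciesRegistry | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a trap-capture CSV into a record DataFrame.

    Parameters
    ----------
    path : file path with header row.
    registry : optional; when given, every species label must resolve in it.
    column_map : optional mapping from the file's column names to the
        canonical ``RECORD_COLUMNS`` (for upstream dialects).
    """
    df = pd.read_csv(path, dtype={"treatment": str, "replicate": str, "trap_id": str, "species": str})
    if column_map:
        df = df.rename(columns=column_map)
    _validate_records(df, registry)
    df = df[RECORD_COLUMNS].copy()
    for col, dt in (("year", np.int32), ("day", np.int32), ("adults", np.int64)):
        df[col] = df[col].astype(dt)
    return df


def write_trap_csv(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def cull(
    records: pd.DataFrame,
    first_year: int = CULL_FIRST_YEAR,
    last_doy: int = CULL_LAST_DOY,
) -> pd.DataFrame:
    """Apply the survey culling rules: keep ``year >= first_year`` and
    ``day <= last_doy``.  Row order is preserved; the operation is idempotent.
    """
    keep = (records["year"] >= first_year) & (records["day"] <= last_doy)
    return records.loc[keep].reset_index(drop=True)


def _trap_week_code(df: pd.DataFrame) -> np.ndarray:
    """Integer code identifying a distinct (trap_id, day) pair."""
    trap = df["trap_id"]
    codes = trap.cat.codes.to_numpy() if isinstance(trap.dtype, pd.CategoricalDtype) \
        else pd.factorize(trap)[0]
    return codes.astype(np.int64) * 367 + df["day"].to_numpy(np.int64)


def aggregate(records: pd.DataFrame, registry: SpeciesRegistry) -> pd.DataFrame:
    """Aggregate culled records to treatment x replicate x year analysis units.

    Emits one row per (unit, species) with ``captures`` = summed adults and
    ``effort`` = number of distinct trap-weeks reporting that species
    (zero-count rows included: effort is a property of the trap, not of
    abundance), plus group rows for taxon_key in ``native``/``exotic``/``all``
    whose effort counts distinct trap-weeks reporting any member species.
    """
    if records.empty:
        return pd.DataFrame(columns=AGGREGATE_COLUMNS)
    df = records[RECORD_COLUMNS].copy()
    # canonical species naming + origin from the registry
    labels = df["species"].unique()
    canon = {lab: registry[lab].name for lab in labels}
    origin = {lab: registry[lab].origin.value for lab in labels}
    df["species"] = df["species"].map(canon)
    df["origin"] = records["species"].map(origin).values
    df["trap_week"] = _trap_week_code(df)

    unit = ["treatment", "replicate", "year"]

    def _agg(frame: pd.DataFrame, key_col: str) -> pd.DataFrame:
        captures = frame.groupby(unit + [key_col], observed=True, sort=True)["adults"].sum()
        effort = (
            frame.drop_duplicates(unit + [key_col, "trap_week"])
            .groupby(unit + [key_col], observed=True, sort=True)
            .size()
        )
        out = pd.DataFrame({"captures": captures, "effort": effort}).reset_index()
        return out.rename(columns={key_col: "taxon_key"})

    per_species = _agg(df, "species")
    by_origin = _agg(df, "origin")
    df["grp_all"] = "all"
    overall = _agg(df, "grp_all")

    out = pd.concat([per_species, by_origin, overall], ignore_index=True)
    out["captures"] = out["captures"].astype(np.int64)
    out["effort"] = out["effort"].astype(np.int64)
    return out[AGGREGATE_COLUMNS]


def write_aggregates_csv(aggregates: pd.DataFrame, path: str | Path) -> None:
    aggregates[AGGREGATE_COLUMNS].to_csv(path, index=False)


def read_aggregates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"treatment": str, "replicate": str, "taxon_key": str})
    missing = [c for c in AGGREGATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing aggregate columns: {missing}")
    return df[AGGREGATE_COLUMNS]
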