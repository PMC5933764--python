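"""Reading, validating and reshaping otolith-increment data.

Increment tables hold one row per fish and annual growth increment: the
radial width laid down between two successive annuli along a fixed growth
axis of the sagittal otolith, together with the cumulative radius up to
that annulus.  Fish tables hold one row per fish with capture metadata
(total length, weight, capture date/location) and the lifetime radius
measured along each of the four natural growth axes (``z1``-``z4``).

The central derived table is the *growth-pair table*: one row per pair of
consecutive annuli within a fish, giving the otolith radius in year t-1
(``Z``) and in year t (``Zprime``).  It is the substrate of all size-size
(Walford) growth fits.

Everything is carried as plain :class:`pandas.DataFrame` objects with the
column schemas declared below; :class:`IncrementRecord` and
:class:`FishRecord` are typed row views for programmatic construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "TemperatureJoinError",
    "IncrementRecord",
    "FishRecord",
    "INCREMENT_COLUMNS",
    "FISH_COLUMNS",
    "TEMPERATURE_COLUMNS",
    "TEMPERATURE_SOURCES",
    "read_increments",
    "read_temperatures",
    "write_increments",
    "write_fish",
    "write_temperatures",
    "records_to_frame",
    "validate_increments",
    "validate_fish",
    "validate_temperatures",
    "build_growth_pairs",
    "first_increments",
    "summer_mean",
    "temperature_series",
    "join_temperature",
]


class SchemaError(ValueError):
    """A CSV is missing required columns or has unparseable cells."""


class ValidationError(ValueError):
    """A table violates a domain invariant (negative width, non-increasing
    cumulative radius, inconsistent formation year...)."""


class TemperatureJoinError(KeyError):
    """A growth year has no temperature value in the requested source."""

    def __init__(self, years: Sequence[int], source: str):
        self.years = sorted(int(y) for y in years)
        self.source = source
        super().__init__(
            f"no temperature for source {source!r} in years {self.years}"
        )


# Canonical CSV schemas.  Extra columns are preserved untouched on read and
# round-tripped on write.
INCREMENT_COLUMNS = (
    "fish_id",
    "spawn_year",
    "increment_index",
    "formation_year",
    "width",
    "cumulative_radius",
)
FISH_COLUMNS = (
    "fish_id",
    "capture_date",
    "capture_location",
    "total_length",
    "weight",
    "age_at_capture",
    "z1",
    "z2",
    "z3",
    "z4",
)
TEMPERATURE_COLUMNS = ("source", "year", "temperature")

#: Recognised temperature aggregation sources, mirroring the four candidate
#: summer-temperature covariates (open-sea coastal average and three lagoon
#: groupings).
TEMPERATURE_SOURCES = (
    "mediterranean",
    "all_lagoons",
    "shallow_lagoons",
    "deep_lagoons",
)


@dataclass(frozen=True)
class IncrementRecord:
    """One annual otolith growth increment of one fish.

    ``increment_index`` 0 is the core-to-first-annulus increment (growth in
    the first year of life); the increment forms in calendar year
    ``spawn_year + increment_index``.
    """

    fish_id: str
    spawn_year: int
    increment_index: int
    formation_year: int
    width: float
    cumulative_radius: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError(
                f"fish {self.fish_id}: increment width must be > 0, "
                f"got {self.width}"
            )
        if self.cumulative_radius <= 0:
            raise ValidationError(
                f"fish {self.fish_id}: cumulative radius must be > 0"
            )
        if self.formation_year != self.spawn_year + self.increment_index:
            raise ValidationError(
                f"fish {self.fish_id}: formation_year {self.formation_year} "
                f"!= spawn_year + increment_index "
                f"({self.spawn_year} + {self.increment_index})"
            )


@dataclass(frozen=True)
class FishRecord:
    """Per-fish capture metadata and lifetime otolith radii (mm)."""

    fish_id: str
    capture_date: date | None = None
    capture_location: str | None = None
    total_length: float | None = None
    weight: float | None = None
    age_at_capture: int | None = None
    z1: float | None = None
    z2: float | None = None
    z3: float | None = None
    z4: float | None = None

    def __post_init__(self):
        if self.total_length is not None and self.total_length <= 0:
            raise ValidationError(
                f"fish {self.fish_id}: total_length must be > 0"
            )


def records_to_frame(records: Iterable[IncrementRecord | FishRecord]) -> pd.DataFrame:
    """Convert a homogeneous list of records to a DataFrame in schema order."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    cols = [f.name for f in dc_fields(records[0])]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_increments(
    increments_path: str | Path,
    fish_path: str | Path | None = None,
    validate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read increment (and optionally fish) CSVs and validate invariants.

    Returns ``(increments, fish)``; ``fish`` is ``None`` when no fish path
    is given.  Dates are parsed as ISO-8601.
    """
    inc = pd.read_csv(increments_path)
    _require_columns(inc, INCREMENT_COLUMNS, increments_path)
    for col in ("spawn_year", "increment_index", "formation_year"):
        inc[col] = inc[col].astype(int)
    for col in ("width", "cumulative_radius"):
        inc[col] = inc[col].astype(float)
    if validate:
        validate_increments(inc)

    fish = None
    if fish_path is not None:
        fish = pd.read_csv(fish_path)
        _require_columns(fish, FISH_COLUMNS, fish_path)
        fish["capture_date"] = pd.to_datetime(
            fish["capture_date"], format="ISO8601", errors="coerce"
        ).dt.date
        for col in ("total_length", "weight", "z1", "z2", "z3", "z4"):
            fish[col] = pd.to_numeric(fish[col], errors="coerce")
        fish["age_at_capture"] = fish["age_at_capture"].astype(int)
        if validate:
            validate_fish(fish, increments=inc)
    return inc, fish


def read_temperatures(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read an annual mean-summer-temperature table (source, year, temperature)."""
    df = pd.read_csv(path)
    _require_columns(df, TEMPERATURE_COLUMNS, path)
    df["year"] = df["year"].astype(int)
    df["temperature"] = df["temperature"].astype(float)
    if validate:
        validate_temperatures(df)
    return df


def write_increments(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, INCREMENT_COLUMNS, path)
    df.to_csv(path, index=False)


def write_fish(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, FISH_COLUMNS, path)
    df.to_csv(path, index=False)


def write_temperatures(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, TEMPERATURE_COLUMNS, path)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_increments(df: pd.DataFrame) -> None:
    """Enforce increment-table invariants, naming offending rows and fish."""
    bad = df.index[df["width"] <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive increment width at rows {list(bad)} "
            f"(fish {sorted(df.loc[bad, 'fish_id'].unique())})"
        )
    bad = df.index[df["cumulative_radius"] <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive cumulative radius at rows {list(bad)}"
        )
    mismatch = df.index[
        df["formation_year"] != df["spawn_year"] + df["increment_index"]
    ]
    if len(mismatch):
        raise ValidationError(
            "formation_year != spawn_year + increment_index at rows "
            f"{list(mismatch)}"
        )
    for fish_id, grp in df.groupby("fish_id", sort=False):
        grp = grp.sort_values("increment_index")
        idx = grp["increment_index"].to_numpy()
        if len(idx) and (idx[0] != 0 or np.any(np.diff(idx) != 1)):
            raise ValidationError(
                f"fish {fish_id!r}: increment indices must run 0,1,... "
                f"without gaps, got {list(idx)}"
            )
        radii = grp["cumulative_radius"].to_numpy()
        if np.any(np.diff(radii) <= 0):
            raise ValidationError(
                f"fish {fish_id!r}: cumulative radius not strictly "
                f"increasing with increment index"
            )


def validate_fish(df: pd.DataFrame, increments: pd.DataFrame | None = None) -> None:
    bad = df.index[df["total_length"].notna() & (df["total_length"] <= 0)]
    if len(bad):
        raise ValidationError(f"non-positive total_length at rows {list(bad)}")
    if increments is not None and len(increments):
        counts = increments.groupby("fish_id").size()
        merged = df.set_index("fish_id")["age_at_capture"]
        common = counts.index.intersection(merged.index)
        off = [
            fid for fid in common if int(merged[fid]) != int(counts[fid])
        ]
        if off:
            raise ValidationError(
                f"age_at_capture != number of complete annuli for fish {off}"
            )


def validate_temperatures(df: pd.DataFrame) -> None:
    if df.duplicated(subset=["source", "year"]).any():
        dup = df[df.duplicated(subset=["source", "year"], keep=False)]
        raise ValidationError(
            f"duplicate (source, year) temperature rows: "
            f"{dup[['source', 'year']].to_dict('records')}"
        )
    if not np.isfinite(df["temperature"]).all():
        raise ValidationError("non-finite temperature values present")


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_growth_pairs(
    increments: pd.DataFrame, drop_nonpositive_growth: bool = True
) -> pd.DataFrame:
    """Build the Walford growth-pair table from validated increments.

    One row per pair of consecutive annuli within a fish: ``Z`` the
    cumulative radius at the earlier annulus, ``Zprime`` at the later one,
    and ``year`` the calendar year in which the later increment grew (its
    formation year), which is the year whose summer temperature drives that
    increment.  Fish with fewer than two annuli contribute no rows; partial
    edge growth beyond the last annulus never enters the table because only
    complete annuli are recorded as increments.

    Rows with ``Zprime <= Z`` (possible only for measurement-inverted raw
    data) are dropped with a logged warning by default.
    """
    if not len(increments):
        return pd.DataFrame(columns=["fish_id", "year", "Z", "Zprime"])
    rows = []
    n_single = 0
    for fish_id, grp in increments.groupby("fish_id", sort=False):
        grp = grp.sort_values("increment_index")
        radii = grp["cumulative_radius"].to_numpy()
        years = grp["formation_year"].to_numpy()
        if len(radii) < 2:
            n_single += 1
            continue
        for i in range(len(radii) - 1):
            rows.append((fish_id, int(years[i + 1]), radii[i], radii[i + 1]))
    if n_single:
        logger.info("%d fish with <2 annuli contributed no growth pairs", n_single)
    pairs = pd.DataFrame(rows, columns=["fish_id", "year", "Z", "Zprime"])
    inverted = pairs["Zprime"] <= pairs["Z"]
    if inverted.any():
        if not drop_nonpositive_growth:
            raise ValidationError(
                f"{int(inverted.sum())} growth pairs with Zprime <= Z"
            )
        logger.warning(
            "dropped %d growth pairs with non-positive growth "
            "(fish %s)",
            int(inverted.sum()),
            sorted(pairs.loc[inverted, "fish_id"].unique()),
        )
        pairs = pairs[~inverted].reset_index(drop=True)
    return pairs


def first_increments(increments: pd.DataFrame) -> pd.DataFrame:
    """First-annulus radii: otolith size at the first birthday vs the year
    in which that age-0 growth occurred (= the spawn year).

    Returns columns ``fish_id, year, Z``.
    """
    if not len(increments):
        return pd.DataFrame(columns=["fish_id", "year", "Z"])
    first = increments[increments["increment_index"] == 0]
    out = first[["fish_id", "formation_year", "cumulative_radius"]].rename(
        columns={"formation_year": "year", "cumulative_radius": "Z"}
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# temperature aggregation
# ---------------------------------------------------------------------------

def summer_mean(
    daily: pd.DataFrame,
    years: Iterable[int] | None = None,
    months: Iterable[int] = (6, 7, 8),
    source: str = "mediterranean",
    require_complete: bool = False,
) -> pd.DataFrame:
    """Aggregate a daily temperature series to annual summer means.

    Parameters
    ----------
    daily : DataFrame with columns ``date`` (parseable to datetime) and
        ``value`` (degrees C).
    years : the years to report; defaults to every year present.
    months : calendar months of the aggregation window (default Jun-Aug,
        the period of maximal growth for warm-season ectotherm growth).
    require_complete : raise instead of warn when a requested year has no
        in-window observations.

    Returns an annual temperature table (``source, year, temperature``);
    a year with no observations in the window is flagged missing (NaN
    temperature plus a warning), never silently zero.
    """
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    d = d[d["date"].dt.month.isin(set(int(m) for m in months))]
    grouped = d.groupby(d["date"].dt.year)["value"].mean()
    if years is None:
        years = sorted(grouped.index)
    years = [int(y) for y in years]
    values = [float(grouped[y]) if y in grouped.index else np.nan for y in years]
    missing = [y for y, v in zip(years, values) if not np.isfinite(v)]
    if missing:
        msg = f"no in-window observations for years {missing}"
        if require_complete:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return pd.DataFrame(
        {"source": source, "year": years, "temperature": values}
    )


def temperature_series(
    temps: pd.DataFrame, source: str = "mediterranean"
) -> pd.Series:
    """Extract one source's year -> temperature mapping as a Series."""
    sub = temps[temps["source"] == source]
    if not len(sub):
        raise TemperatureJoinError([], source)
    return sub.set_index("year")["temperature"].sort_index()


def join_temperature(
    table: pd.DataFrame,
    temps: pd.DataFrame,
    source: str = "mediterranean",
    year_col: str = "year",
) -> pd.DataFrame:
    """Attach a ``T`` column to a table keyed by growth year.

    Raises :class:`TemperatureJoinError` listing every year with no
    temperature in the requested source.
    """
    series = temperature_series(temps, source)
    years = table[year_col].astype(int)
    missing = sorted(set(years) - set(series.index[np.isfinite(series.values)]))
    if missing:
        raise TemperatureJoinError(missing, source)
    out = table.copy()
    out["T"] = series.reindex(years).to_numpy()
    return out
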