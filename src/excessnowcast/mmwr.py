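"""MMWR epidemiological-week calendar and provisional snapshot tables.

The CDC releases provisional weekly death counts keyed by MMWR week
(Sunday--Saturday, week 1 being the week that contains at least four days
of January) and jurisdiction.  Successive releases ("snapshots") revise
recent weeks upward as late death certificates arrive; non-zero counts
below 10 are masked for privacy.  This module provides the calendar
arithmetic, the fixed 53-jurisdiction registry, and CSV readers/writers
that preserve the masking convention.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JURISDICTIONS",
    "MMWRWeek",
    "Snapshot",
    "SnapshotSeries",
    "HistoricalSeries",
    "week_ending_date",
    "mmwr_weeks_in_year",
    "date_to_mmwr_week",
    "elapsed_reporting_time",
    "read_snapshot_csv",
    "write_snapshot_csv",
    "read_historical_csv",
    "write_historical_csv",
    "validate_monotone",
]

# 50 states with New York split into New York City and rest-of-state,
# plus the District of Columbia and Puerto Rico: 53 reporting jurisdictions.
JURISDICTIONS: tuple[str, ...] = (
    "Alabama", "Alaska", "Arizona", "Arkansas", "California", "Colorado",
    "Connecticut", "Delaware", "District of Columbia", "Florida", "Georgia",
    "Hawaii", "Idaho", "Illinois", "Indiana", "Iowa", "Kansas", "Kentucky",
    "Louisiana", "Maine", "Maryland", "Massachusetts", "Michigan",
    "Minnesota", "Mississippi", "Missouri", "Montana", "Nebraska", "Nevada",
    "New Hampshire", "New Jersey", "New Mexico", "New York",
    "New York City", "North Carolina", "North Dakota", "Ohio", "Oklahoma",
    "Oregon", "Pennsylvania", "Puerto Rico", "Rhode Island",
    "South Carolina", "South Dakota", "Tennessee", "Texas", "Utah",
    "Vermont", "Virginia", "Washington", "West Virginia", "Wisconsin",
    "Wyoming",
)

#: columns shared by every snapshot / historical table
TABLE_COLUMNS = ["jurisdiction", "mmwr_year", "mmwr_week", "deaths", "masked"]

_SATURDAY = 5  # datetime.weekday() convention, Monday == 0
_WEDNESDAY = 2

# Offset from the week-ending Saturday back to the mean death date.  Deaths
# are spread over the Sunday--Saturday week, so the average death occurred
# mid-week, 3.5 days before the Saturday that labels the week.
MIDWEEK_OFFSET_DAYS = 3.5


class MMWRWeek(NamedTuple):
    """An epidemiological week, e.g. ``MMWRWeek(2020, 34)``."""

    year: int
    week: int

    def __add__(self, weeks: int) -> "MMWRWeek":  # type: ignore[override]
        return date_to_mmwr_week(week_ending_date(self) + dt.timedelta(weeks=weeks))

    def __sub__(self, other: "MMWRWeek | int"):
        if isinstance(other, int):
            return self + (-other)
        return (week_ending_date(self) - week_ending_date(other)).days // 7


def _first_week_end(year: int) -> dt.date:
    """Saturday ending MMWR week 1: the first Saturday on or after 4 January."""
    jan4 = dt.date(year, 1, 4)
    return jan4 + dt.timedelta(days=(_SATURDAY - jan4.weekday()) % 7)


def mmwr_weeks_in_year(year: int) -> int:
    """Number of MMWR weeks (52 or 53) in ``year``."""
    return (_first_week_end(year + 1) - _first_week_end(year)).days // 7


def week_ending_date(week: MMWRWeek | tuple[int, int]) -> dt.date:
    """Saturday ending the given MMWR week.

    Raises ``ValueError`` if the week number is outside ``1..weeks_in_year``
    (week 53 only exists in 53-week MMWR years).
    """
    year, w = week
    n = mmwr_weeks_in_year(year)
    if not 1 <= w <= n:
        raise ValueError(f"MMWR year {year} has {n} weeks; got week {w}")
    return _first_week_end(year) + dt.timedelta(weeks=w - 1)


def date_to_mmwr_week(day: dt.date) -> MMWRWeek:
    """MMWR week containing ``day``."""
    for year in (day.year + 1, day.year, day.year - 1):
        start = _first_week_end(year) - dt.timedelta(days=6)
        if day >= start:
            week = (day - start).days // 7 + 1
            if week <= mmwr_weeks_in_year(year):
                return MMWRWeek(year, week)
    raise ValueError(f"no MMWR week found for {day}")  # pragma: no cover


def elapsed_reporting_time(snapshot_date: dt.date, week: MMWRWeek | tuple[int, int]) -> float:
    """Elapsed time, in weeks, from the mean death date of ``week`` to publication.

    Measured from the mid-point of the death week (week-ending Saturday minus
    3.5 days) to ``snapshot_date``.  For Wednesday publications this places
    the first nominal 2-week reporting bin at roughly the first 10 days after
    death.  Negative values are permitted; callers exclude such weeks.
    """
    delta = (snapshot_date - week_ending_date(week)).days + MIDWEEK_OFFSET_DAYS
    return delta / 7.0


# ---------------------------------------------------------------------------
# tables


def _validate_table(df: pd.DataFrame, registry: Sequence[str]) -> pd.DataFrame:
    unknown = set(df["jurisdiction"]) - set(registry)
    if unknown:
        raise ValueError(f"unknown jurisdictions: {sorted(unknown)}")
    dup = df.duplicated(subset=["jurisdiction", "mmwr_year", "mmwr_week"])
    if dup.any():
        bad = df.loc[dup, ["jurisdiction", "mmwr_year", "mmwr_week"]].iloc[0]
        raise ValueError(f"duplicate cell: {tuple(bad)}")
    counts = df["deaths"]
    if (counts.dropna() < 0).any():
        raise ValueError("negative death count")
    return df


@dataclass
class Snapshot:
    """One provisional release: counts by (jurisdiction, MMWR week).

    ``data`` columns: jurisdiction, mmwr_year, mmwr_week, deaths (float,
    NaN when masked), masked (bool).  Masked cells stand in for true counts
    in 1..9.
    """

    publication_date: dt.date
    data: pd.DataFrame
    registry: Sequence[str] = JURISDICTIONS

    def __post_init__(self) -> None:
        if self.publication_date.weekday() != _WEDNESDAY:
            raise ValueError(f"publication date {self.publication_date} is not a Wednesday")
        self.data = _validate_table(
            self.data.reset_index(drop=True)[TABLE_COLUMNS], self.registry
        )

    def counts(self, jurisdiction: str) -> pd.DataFrame:
        return self.data[self.data["jurisdiction"] == jurisdiction]


@dataclass
class SnapshotSeries:
    """Time-ordered stack of snapshots; the last one plays the role of 'final'."""

    snapshots: list[Snapshot]

    def __post_init__(self) -> None:
        dates = [s.publication_date for s in self.snapshots]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("snapshot publication dates must strictly increase")
        registries = {tuple(s.registry) for s in self.snapshots}
        if len(registries) > 1:
            raise ValueError("snapshots use different jurisdiction registries")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    @property
    def final_index(self) -> int:
        return len(self.snapshots) - 1

    @property
    def jurisdictions(self) -> list[str]:
        return sorted(set(self.final.data["jurisdiction"]))


@dataclass
class HistoricalSeries:
    """Finalised weekly death counts for the baseline-training years.

    Same table schema as :class:`Snapshot` plus a ``source_year`` tag; no
    masking ambiguity (counts are final).
    """

    data: pd.DataFrame
    registry: Sequence[str] = JURISDICTIONS

    def __post_init__(self) -> None:
        cols = TABLE_COLUMNS + ["source_year"]
        df = self.data.reset_index(drop=True)
        if "source_year" not in df.columns:
            df["source_year"] = df["mmwr_year"]
        if "masked" not in df.columns:
            df["masked"] = False
        self.data = _validate_table(df[cols], self.registry)[cols]

    @property
    def years(self) -> list[int]:
        return sorted(self.data["mmwr_year"].unique())

    def counts(self, jurisdiction: str) -> pd.DataFrame:
        return self.data[self.data["jurisdiction"] == jurisdiction]


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: UTF-8, comma-separated, header row required.  The mask
# token (default: empty field) replaces any written count in 1..9 when
# masking is applied; zero is never masked.

CSV_COLUMNS = ["jurisdiction", "mmwr_year", "mmwr_week", "deaths"]


def _frame_to_csv(df: pd.DataFrame, path, mask_token: str, apply_masking: bool,
                  extra: list[str] | None = None) -> None:
    out = df.copy()
    deaths = out["deaths"]
    as_text = deaths.map(lambda v: "" if pd.isna(v) else str(int(v)))
    masked = out["masked"].astype(bool)
    if apply_masking:
        masked = masked | deaths.between(1, 9)
    as_text[masked] = mask_token
    out["deaths"] = as_text
    cols = CSV_COLUMNS + (extra or [])
    out[cols].to_csv(path, index=False)


def _frame_from_csv(path, mask_token: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"jurisdiction": str, "deaths": str},
                     keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot CSV missing columns: {sorted(missing)}")
    raw = df["deaths"].str.strip()
    masked = raw == mask_token
    deaths = pd.to_numeric(raw.where(~masked, np.nan))
    df = df.assign(deaths=deaths.astype(float), masked=masked)
    df["mmwr_year"] = df["mmwr_year"].astype(int)
    df["mmwr_week"] = df["mmwr_week"].astype(int)
    return df


def read_snapshot_csv(path, publication_date: dt.date, mask_token: str = "",
                      registry: Sequence[str] = JURISDICTIONS) -> Snapshot:
    """Read one snapshot table; ``mask_token`` cells become masked flags."""
    return Snapshot(publication_date, _frame_from_csv(path, mask_token), registry)


def write_snapshot_csv(snapshot: Snapshot, path, apply_masking: bool = False,
                       mask_token: str = "") -> None:
    """Write a snapshot; with ``apply_masking`` every count in 1..9 is replaced
    by the mask token (zero counts are written as "0")."""
    _frame_to_csv(snapshot.data, path, mask_token, apply_masking)


def read_historical_csv(path, mask_token: str = "",
                        registry: Sequence[str] = JURISDICTIONS) -> HistoricalSeries:
    df = _frame_from_csv(path, mask_token)
    if "source_year" not in df.columns:
        df["source_year"] = df["mmwr_year"]
    return HistoricalSeries(df, registry)


def write_historical_csv(hist: HistoricalSeries, path, apply_masking: bool = False,
                         mask_token: str = "") -> None:
    _frame_to_csv(hist.data, path, mask_token, apply_masking, extra=["source_year"])


def validate_monotone(series: SnapshotSeries) -> pd.DataFrame:
    """Report (jurisdiction, week, snapshot pair) cells whose counts decrease
    between consecutive snapshots.

    Real CDC files occasionally re-arrange weekly numbers (observed for
    Vermont), so decreasing cells are flagged for review, never rejected.
    """
    rows = []
    prev: pd.DataFrame | None = None
    for idx, snap in enumerate(series.snapshots):
        cur = snap.data.set_index(["jurisdiction", "mmwr_year", "mmwr_week"])["deaths"]
        if prev is not None:
            joined = pd.concat({"before": prev, "after": cur}, axis=1).dropna()
            bad = joined[joined["after"] < joined["before"]]
            for key, row in bad.iterrows():
                rows.append((*key, idx - 1, idx, row["before"], row["after"]))
        prev = cur
    return pd.DataFrame(
        rows,
        columns=["jurisdiction", "mmwr_year", "mmwr_week",
                 "snapshot_before", "snapshot_after", "count_before", "count_after"],
    )
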