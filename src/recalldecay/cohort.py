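"""Backward person-time construction from retrospective survey records.

A survey interview elicits, for each household member, the date of the most
recent injury (if any) within the last year. Retrospective follow-up runs
backwards from the interview date until the most recent reported injury or
until a full year without one. The year is split into 11 periods of 30 days
plus a final period of 35 days (days 330-364 before the interview), referred
to as months 1..12 before the interview. Person-time and event counts are
accumulated per (covariate stratum, household, month) cell; those cells are
the units the Poisson models are fitted to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .factors import FACTORS, FACTOR_LEVELS, INJURY_CAUSES, check_level

logger = logging.getLogger(__name__)

#: Days in each month before the interview (months 1..12).
MONTH_LENGTHS: tuple[int, ...] = (30,) * 11 + (35,)
#: First day (0-based, day 0 = interview day) of each month before interview.
MONTH_STARTS: tuple[int, ...] = tuple(30 * m for m in range(12))
DAYS_PER_YEAR: int = 365

#: Columns identifying a stratum in a person-time table.
STRATUM_COLUMNS: tuple[str, ...] = FACTORS + ("household_id",)
TABLE_COLUMNS: tuple[str, ...] = STRATUM_COLUMNS + ("month", "person_years", "events")


def month_of_day(days_before_interview: int) -> int:
    """Month index (1..12) containing a given day before the interview.

    Day 0 is the interview day. Days ``d < 330`` fall in month ``d // 30 + 1``
    (half-open 30-day periods, so a day exactly on a boundary belongs to the
    later, more recent month); days 330-364 form the 35-day month 12.
    """
    d = int(days_before_interview)
    if d != days_before_interview:
        raise ValueError("days_before_interview must be an integer day count")
    if d < 0 or d >= DAYS_PER_YEAR:
        raise ValueError(
            f"days_before_interview must be in [0, {DAYS_PER_YEAR}); got {d}"
        )
    return min(d // 30 + 1, 12)


@dataclass(frozen=True)
class PersonRecord:
    """One surveyed individual with covariates and the most recent injury, if any."""

    person_id: str
    household_id: str
    sex: str
    age_group: str
    education: str
    location: str
    ses_tertile: str
    injury_days_before_interview: int | None = None
    injury_cause: str | None = None

    def __post_init__(self) -> None:
        for factor in FACTORS:
            check_level(factor, getattr(self, factor))
        d = self.injury_days_before_interview
        if d is not None:
            if d < 0 or d >= DAYS_PER_YEAR:
                raise ValueError(
                    f"injury day {d} outside the recall window [0, {DAYS_PER_YEAR})"
                )
        if self.injury_cause is not None:
            if d is None:
                raise ValueError("injury_cause given without an injury date")
            if self.injury_cause not in INJURY_CAUSES:
                raise ValueError(f"unknown injury cause {self.injury_cause!r}")


@dataclass
class PersonTimeTable:
    """Aggregated person-time and event counts per (stratum, household, month)."""

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(TABLE_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"person-time table missing columns {missing}")

    @property
    def total_person_years(self) -> float:
        return float(self.data["person_years"].sum())

    @property
    def total_events(self) -> int:
        return int(self.data["events"].sum())

    @property
    def months(self) -> frozenset[int]:
        return frozenset(int(m) for m in self.data["month"].unique())

    def restrict(self, months: Iterable[int]) -> "PersonTimeTable":
        """Table restricted to the given months before interview."""
        months = set(int(m) for m in months)
        return PersonTimeTable(
            self.data[self.data["month"].isin(months)].reset_index(drop=True)
        )

    def window_totals(self, months: Iterable[int]) -> tuple[int, float]:
        """(events, person_years) pooled over a set of months."""
        sub = self.restrict(months).data
        return int(sub["events"].sum()), float(sub["person_years"].sum())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PersonTimeTable":
        df = pd.read_csv(path, dtype={"household_id": str})
        return cls(df[list(TABLE_COLUMNS)])


def build_person_time(
    records: Sequence[PersonRecord],
    cause_filter: str | None = None,
) -> PersonTimeTable:
    """Build the backward monthly person-time/event table from survey records.

    Every person contributes exposure backwards from the interview: a person
    without a recorded injury contributes the full 30/365 person-years to
    months 1..11 and 35/365 to month 12 (exactly one person-year in total).
    A person injured ``d`` days before the interview contributes full months
    up to the injury month, partial exposure in the injury month (from the
    month's start back to and including the injury day), nothing beyond, and
    one event in the injury month.

    With ``cause_filter`` set, injuries of other causes terminate exposure in
    the same way but count as censoring, not events.
    """
    if cause_filter is not None and cause_filter not in INJURY_CAUSES:
        raise ValueError(f"unknown injury cause {cause_filter!r}")
    if len(records) == 0:
        return PersonTimeTable()

    ids = [r.person_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate person_id(s): {dupes[:5]}")

    n = len(records)
    days = np.array(
        [
            -1 if r.injury_days_before_interview is None else r.injury_days_before_interview
            for r in records
        ],
        dtype=np.int64,
    )
    terminated = days >= 0
    if cause_filter is None:
        is_event = terminated
    else:
        causes = np.array([r.injury_cause or "" for r in records])
        is_event = terminated & (causes == cause_filter)

    # Exposure in days per (person, month): follow-up covers days 0..d inclusive
    # (the injury day itself is exposed time), the full year if uninjured.
    cutoff = np.where(terminated, days + 1, DAYS_PER_YEAR)
    starts = np.asarray(MONTH_STARTS)
    lengths = np.asarray(MONTH_LENGTHS)
    exposure_days = np.clip(cutoff[:, None] - starts[None, :], 0, lengths[None, :])

    events = np.zeros((n, 12), dtype=np.int64)
    if terminated.any():
        ev_rows = np.nonzero(is_event)[0]
        ev_months = np.array([month_of_day(d) for d in days[ev_rows]], dtype=np.int64)
        events[ev_rows, ev_months - 1] = 1

    frame = pd.DataFrame(
        {f: pd.Categorical([getattr(r, f) for r in records], categories=FACTOR_LEVELS[f])
         for f in FACTORS}
    )
    frame["household_id"] = [r.household_id for r in records]

    long = frame.loc[frame.index.repeat(12)].reset_index(drop=True)
    long["month"] = np.tile(np.arange(1, 13), n)
    long["person_years"] = exposure_days.ravel() / DAYS_PER_YEAR
    long["events"] = events.ravel()
    long = long[long["person_years"] > 0]

    agg = (
        long.groupby(list(STRATUM_COLUMNS) + ["month"], observed=True, sort=True)[
            ["person_years", "events"]
        ]
        .sum()
        .reset_index()
    )
    for f in FACTORS:
        agg[f] = agg[f].astype(str)
    return PersonTimeTable(agg[list(TABLE_COLUMNS)])


def read_records(path) -> list[PersonRecord]:
    """Read per-person survey records from a delimited text file.

    Expected columns: ``person_id, household_id, sex, age_group, education,
    location, ses_tertile`` plus either a precomputed integer
    ``injury_days_before_interview`` or the pair ``interview_date`` /
    ``injury_date`` (ISO-8601; the precomputed column takes precedence), and
    optionally ``injury_cause``. Rows with missing covariates are dropped with
    a logged count.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "household_id": str})
    required = ["person_id", "household_id", *FACTORS]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input file missing columns {missing_cols}")

    complete = df[list(FACTORS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d record(s) with missing covariates", n_dropped)
    df = df[complete]

    if "injury_days_before_interview" in df.columns:
        days = df["injury_days_before_interview"]
    elif "injury_date" in df.columns and "interview_date" in df.columns:
        interview = pd.to_datetime(df["interview_date"])
        injury = pd.to_datetime(df["injury_date"])
        days = (interview - injury).dt.days
    else:
        days = pd.Series(np.nan, index=df.index)

    causes = df["injury_cause"] if "injury_cause" in df.columns else pd.Series(
        np.nan, index=df.index
    )

    records = []
    for (_, row), d, cause in zip(df.iterrows(), days, causes):
        has_injury = pd.notna(d)
        records.append(
            PersonRecord(
                person_id=str(row["person_id"]),
                household_id=str(row["household_id"]),
                **{f: str(row[f]) for f in FACTORS},
                injury_days_before_interview=int(d) if has_injury else None,
                injury_cause=str(cause) if has_injury and pd.notna(cause) else None,
            )
        )
    return records


def write_records(records: Sequence[PersonRecord], path) -> None:
    """Write person records as CSV (inverse of :func:`read_records`)."""
    pd.DataFrame(
        {
            "person_id": [r.person_id for r in records],
            "household_id": [r.household_id for r in records],
            **{f: [getattr(r, f) for r in records] for f in FACTORS},
            "injury_days_before_interview": [
                r.injury_days_before_interview for r in records
            ],
            "injury_cause": [r.injury_cause for r in records],
        }
    ).to_csv(path, index=False)
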