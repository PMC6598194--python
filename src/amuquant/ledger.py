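"""Flock production cycles: weekly populations, deaths and biomass.

A flock ledger records one production cycle of a small-scale chicken flock
from restocking with day-old chicks to sale: the number of birds present at
the start of each production week, deaths during the week, and the
medication events (product, amount) recorded by the farmer.  Flock biomass
at any week is the bird count times the mean bird weight from a growth
curve (weekly mean weights of reference birds); production week 1 is the
week of restocking, and calendar position is tracked as ISO year/week.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GrowthCurve",
    "MedicationEvent",
    "WeekEntry",
    "FlockLedger",
    "biomass",
    "cumulative_mortality",
    "kg_sold",
    "default_growth_curve",
    "read_record_books",
    "read_growth_curve",
    "calendar_index",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Mean bird weight (kg) by production week, 1-based.

    Lookup is exact-by-week — records are weekly, so nothing finer is
    defensible — and weeks beyond the table raise rather than extrapolate.
    Weights must be non-decreasing unless the table is flagged ``empirical``
    (real weighings can dip week-on-week).
    """

    week_weights: Mapping[int, float]
    empirical: bool = False

    def __post_init__(self) -> None:
        weeks = sorted(self.week_weights)
        if not weeks:
            raise ValidationError("growth curve is empty")
        if weeks[0] != 1 or weeks != list(range(1, weeks[-1] + 1)):
            raise ValidationError("growth curve weeks must be consecutive from 1")
        prev = 0.0
        for w in weeks:
            weight = self.week_weights[w]
            if weight <= 0:
                raise ValidationError(f"growth curve weight at week {w} must be > 0")
            if not self.empirical and weight < prev:
                raise ValidationError(
                    f"growth curve decreases at week {w}; flag empirical=True "
                    "to allow measured dips"
                )
            prev = weight

    @property
    def max_week(self) -> int:
        return max(self.week_weights)

    def weight(self, week: int) -> float:
        try:
            return self.week_weights[week]
        except KeyError:
            raise ValidationError(
                f"growth curve undefined at week {week} (support 1..{self.max_week})"
            ) from None


@dataclass(frozen=True)
class MedicationEvent:
    """One product administration recorded in a flock-week.

    ``amount`` is grams of product for powders, millilitres for liquids.
    """

    product_id: str
    amount: float

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValidationError(
                f"event amount for product {self.product_id!r} must be > 0"
            )


@dataclass(frozen=True)
class WeekEntry:
    production_week: int
    iso_year: int
    iso_week: int
    birds_present: int
    deaths: int
    events: tuple[MedicationEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.production_week < 1:
            raise ValidationError("production_week must be >= 1")
        if not (1 <= self.iso_week <= 53):
            raise ValidationError(f"iso_week {self.iso_week} out of range 1..53")
        if self.birds_present < 0 or self.deaths < 0:
            raise ValidationError("bird counts must be non-negative")
        if self.deaths > self.birds_present:
            raise ValidationError(
                f"week {self.production_week}: deaths ({self.deaths}) exceed "
                f"birds present ({self.birds_present})"
            )


@dataclass(frozen=True)
class FlockLedger:
    """One complete production cycle of one flock."""

    flock_id: str
    farm_id: str
    restocked: int
    weeks: tuple[WeekEntry, ...]
    sold: int

    def __post_init__(self) -> None:
        if not self.weeks:
            raise ValidationError(f"flock {self.flock_id!r}: no week entries")
        if self.restocked <= 0:
            raise ValidationError(f"flock {self.flock_id!r}: restocked must be > 0")
        expected = list(range(1, len(self.weeks) + 1))
        if [w.production_week for w in self.weeks] != expected:
            raise ValidationError(
                f"flock {self.flock_id!r}: production weeks must run 1..n"
            )
        if self.weeks[0].birds_present != self.restocked:
            raise ValidationError(
                f"flock {self.flock_id!r}: week-1 birds must equal restocked"
            )
        for prev, cur in zip(self.weeks, self.weeks[1:]):
            if cur.birds_present > prev.birds_present - prev.deaths:
                raise ValidationError(
                    f"flock {self.flock_id!r}: population rises at week "
                    f"{cur.production_week} (mid-cycle restock is unsupported)"
                )
        last = self.weeks[-1]
        if self.sold != last.birds_present - last.deaths:
            raise ValidationError(
                f"flock {self.flock_id!r}: sold ({self.sold}) must equal final "
                f"birds minus final deaths ({last.birds_present - last.deaths})"
            )
        if self.sold + self.total_deaths > self.restocked:
            raise ValidationError(
                f"flock {self.flock_id!r}: sold + deaths exceed restocked"
            )

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def total_deaths(self) -> int:
        return sum(w.deaths for w in self.weeks)

    def week(self, production_week: int) -> WeekEntry:
        if not 1 <= production_week <= self.n_weeks:
            raise ValidationError(
                f"flock {self.flock_id!r}: week {production_week} outside cycle "
                f"1..{self.n_weeks}"
            )
        return self.weeks[production_week - 1]


def biomass(flock: FlockLedger, week: int, curve: GrowthCurve) -> float:
    """Total live weight (kg) of the flock at a production week."""
    entry = flock.week(week)
    return entry.birds_present * curve.weight(week)


def cumulative_mortality(flock: FlockLedger) -> float:
    """Deaths from restocking to sale over birds restocked, in [0, 1]."""
    return flock.total_deaths / flock.restocked


def kg_sold(flock: FlockLedger, curve: GrowthCurve) -> float:
    """Live weight sold: birds sold times mean weight at the final week."""
    if flock.sold == 0:
        return 0.0
    return flock.sold * curve.weight(flock.n_weeks)


def default_growth_curve(max_week: int = 24) -> GrowthCurve:
    """Gompertz-shaped weekly weight table for a native-breed meat chicken.

    Calibrated so that week-18 mean weight is ~1.4 kg (slow-growing breeds
    raised over 16–20-week cycles), starting near 40 g at restocking.  This
    is a synthetic stand-in with the right scale and shape; analyses of real
    record books should supply measured weekly weighings instead.
    """
    # w(t) = A * exp(-b * exp(-k t)); A chosen so w(18) ~= 1.4 kg
    A, b, k = 2.6, 4.1, 0.115
    weights = {
        w: round(float(A * np.exp(-b * np.exp(-k * w))), 4)
        for w in range(1, max_week + 1)
    }
    return GrowthCurve(week_weights=weights)


def calendar_index(iso_year: int, iso_week: int, origin: tuple[int, int]) -> int:
    """Continuous study-week index of an ISO (year, week) pair.

    ``origin`` is the ISO (year, week) assigned index 0.  Computed via real
    ISO calendar dates, so 52/53-week years are handled correctly.
    """
    d = _dt.date.fromisocalendar(iso_year, iso_week, 1)
    d0 = _dt.date.fromisocalendar(origin[0], origin[1], 1)
    return (d - d0).days // 7


# ---------------------------------------------------------------------------
# CSV interfaces


def read_growth_curve(path: str | Path, empirical: bool = False) -> GrowthCurve:
    """Read a ``week, weight_kg`` CSV into a growth curve."""
    df = pd.read_csv(path)
    if not {"week", "weight_kg"} <= set(df.columns):
        raise ValidationError("growth curve CSV needs columns week, weight_kg")
    return GrowthCurve(
        week_weights={int(r.week): float(r.weight_kg) for r in df.itertuples()},
        empirical=empirical,
    )


def read_record_books(
    records_path: str | Path, events_path: str | Path | None = None
) -> dict[str, FlockLedger]:
    """Read flock record books (one row per flock-week) plus optional events.

    Records columns: ``flock_id, farm_id, production_week, iso_year,
    iso_week, birds_present, deaths``.  Events columns: ``flock_id,
    production_week, product_id, amount, unit``.
    """
    records = pd.read_csv(records_path)
    required = {
        "flock_id",
        "farm_id",
        "production_week",
        "iso_year",
        "iso_week",
        "birds_present",
        "deaths",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"record book missing columns {sorted(missing)}")

    events_by_key: dict[tuple[str, int], list[MedicationEvent]] = {}
    if events_path is not None:
        events = pd.read_csv(events_path)
        ev_required = {"flock_id", "production_week", "product_id", "amount"}
        ev_missing = ev_required - set(events.columns)
        if ev_missing:
            raise ValidationError(f"events file missing columns {sorted(ev_missing)}")
        for row in events.itertuples(index=False):
            key = (str(row.flock_id), int(row.production_week))
            events_by_key.setdefault(key, []).append(
                MedicationEvent(product_id=str(row.product_id), amount=float(row.amount))
            )

    ledgers: dict[str, FlockLedger] = {}
    for flock_id, group in records.groupby("flock_id", sort=True):
        group = group.sort_values("production_week")
        dup = group["production_week"].duplicated()
        if dup.any():
            weeks = group.loc[dup, "production_week"].tolist()
            raise ValidationError(
                f"flock {flock_id!r}: duplicate production weeks {weeks}"
            )
        entries = tuple(
            WeekEntry(
                production_week=int(r.production_week),
                iso_year=int(r.iso_year),
                iso_week=int(r.iso_week),
                birds_present=int(r.birds_present),
                deaths=int(r.deaths),
                events=tuple(
                    events_by_key.get((str(flock_id), int(r.production_week)), ())
                ),
            )
            for r in group.itertuples(index=False)
        )
        last = entries[-1]
        ledgers[str(flock_id)] = FlockLedger(
            flock_id=str(flock_id),
            farm_id=str(group.iloc[0]["farm_id"]),
            restocked=int(entries[0].birds_present),
            weeks=entries,
            sold=last.birds_present - last.deaths,
        )
    if not ledgers:
        raise ValidationError(f"record book {records_path} contains no flocks")
    return ledgers
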