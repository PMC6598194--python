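"""Flock-level antimicrobial-use metrics.

Three metrics summarise a production cycle:

``mg/kg at treatment``
    Milligrams of antimicrobial active ingredient (AAI) divided by flock
    biomass in the week each administration happened, summed over the cycle.
``mg/kg sold``
    Total AAI milligrams over the cycle divided by the live weight of birds
    sold; undefined for flocks with 100% mortality (nothing sold).
``treatment incidence (TI)``
    Animal-daily-dose days per 1,000 chicken-days.  An event contributes
    ``amount / (daily product dose × flock biomass)`` dose-days, split
    equally among the product's 1, 2 or 4 AAIs; TI = 1000 × dose-days /
    (7 × cycle weeks), so TI = 1000 corresponds to dosing at exactly the
    therapeutic rate every day of the cycle.

Events whose product is injectable or a human medicine are excluded from
all three metrics (their reach cannot be quantified from labels) but are
counted in ``excluded_events`` so the accounting is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import IntakeModel, Product, is_quantifiable, product_daily_dose
from .errors import ValidationError
from .ledger import FlockLedger, GrowthCurve, MedicationEvent, biomass, kg_sold

__all__ = [
    "PerAaiMetrics",
    "FlockMetrics",
    "CohortSummary",
    "event_aai_mass",
    "event_doses",
    "mg_per_kg_at_treatment",
    "mg_per_kg_sold",
    "treatment_incidence",
    "compute_flock_metrics",
    "cohort_summary",
    "top_quartile_share",
    "metrics_frame",
]

TiDenominator = Literal["biomass", "per-bird"]


def event_aai_mass(event: MedicationEvent, product: Product) -> dict[str, float]:
    """Milligrams of each AAI delivered by one medication event.

    ``amount`` (g of powder / ml of liquid) times the per-unit concentration
    (mg per g or ml).  Mass is conserved: the values sum to amount × total
    concentration.  Non-antimicrobial products yield an empty mapping.
    """
    return {
        ing.aai.name: event.amount * ing.concentration for ing in product.ingredients
    }


def event_doses(
    event: MedicationEvent,
    product: Product,
    flock_biomass_kg: float,
    intake: IntakeModel | None = None,
) -> tuple[float, dict[str, float]]:
    """Animal-daily-dose days delivered by one event, total and per AAI.

    The product-level count is the administered product mass divided by the
    mass needed to dose the whole flock for one day
    (``product_daily_dose × biomass``).  Each of the product's k ingredients
    receives 1/k of the product dose-days (k ∈ {1, 2, 4}), mirroring how a
    combination product delivers a fraction of a full dose of each AAI.
    """
    if flock_biomass_kg <= 0:
        raise ValidationError(
            f"event for product {event.product_id!r}: flock biomass must be "
            "positive in the administration week"
        )
    amount_mg = event.amount * 1000.0  # g (or ml at 1 g/ml) -> mg
    dose_days = amount_mg / (product_daily_dose(product, intake) * flock_biomass_kg)
    k = len(product.ingredients)
    per_aai = {ing.aai.name: dose_days / k for ing in product.ingredients}
    return dose_days, per_aai


@dataclass(frozen=True)
class PerAaiMetrics:
    mg_per_kg_at_treatment: float = 0.0
    mg_per_kg_sold: float | None = None
    treatment_incidence: float = 0.0


@dataclass(frozen=True)
class FlockMetrics:
    """The three AMU metrics for one flock, with per-AAI breakdowns."""

    flock_id: str
    farm_id: str
    mg_per_kg_at_treatment: float
    mg_per_kg_sold: float | None  # None when no birds were sold
    treatment_incidence: float
    per_aai: Mapping[str, PerAaiMetrics]
    excluded_events: int
    cumulative_mortality: float
    n_weeks: int


def _iter_quantifiable(
    flock: FlockLedger, products: Mapping[str, Product]
) -> tuple[list[tuple[int, MedicationEvent, Product]], int]:
    """Split a flock's events into (week, event, product) triples and an
    excluded-event tally; unknown products are a hard error."""
    kept: list[tuple[int, MedicationEvent, Product]] = []
    excluded = 0
    for entry in flock.weeks:
        for event in entry.events:
            product = products.get(event.product_id)
            if product is None:
                raise ValidationError(
                    f"flock {flock.flock_id!r} week {entry.production_week}: "
                    f"event references unknown product {event.product_id!r}"
                )
            if is_quantifiable(product):
                kept.append((entry.production_week, event, product))
            elif product.is_antimicrobial:
                excluded += 1
            # non-antimicrobial products are simply not AMU events
    return kept, excluded


def mg_per_kg_at_treatment(
    flock: FlockLedger,
    products: Mapping[str, Product],
    curve: GrowthCurve,
) -> float:
    """Cumulative AAI mass over biomass in each administration week."""
    total = 0.0
    for week, event, product in _iter_quantifiable(flock, products)[0]:
        b = biomass(flock, week, curve)
        if b <= 0:
            raise ValidationError(
                f"flock {flock.flock_id!r}: medication recorded in week {week} "
                "with zero biomass"
            )
        total += sum(event_aai_mass(event, product).values()) / b
    return total


def mg_per_kg_sold(
    flock: FlockLedger,
    products: Mapping[str, Product],
    curve: GrowthCurve,
) -> float | None:
    """Cycle AAI mass over kg of chicken sold; None when nothing was sold."""
    sold_kg = kg_sold(flock, curve)
    total_mg = sum(
        sum(event_aai_mass(event, product).values())
        for _, event, product in _iter_quantifiable(flock, products)[0]
    )
    if sold_kg == 0:
        return None
    return total_mg / sold_kg


def treatment_incidence(
    flock: FlockLedger,
    products: Mapping[str, Product],
    curve: GrowthCurve,
    intake: IntakeModel | None = None,
    ti_denominator: TiDenominator = "biomass",
) -> float:
    """Dose-days per 1,000 chicken-days over the cycle."""
    return compute_flock_metrics(
        flock, products, curve, intake, ti_denominator=ti_denominator
    ).treatment_incidence


def compute_flock_metrics(
    flock: FlockLedger,
    products: Mapping[str, Product],
    curve: GrowthCurve,
    intake: IntakeModel | None = None,
    ti_denominator: TiDenominator = "biomass",
) -> FlockMetrics:
    """All three metrics plus per-AAI breakdowns in one pass.

    ``ti_denominator`` selects the TI normalisation: ``"biomass"`` (default)
    counts flock-level dose-days against 7 × cycle-weeks; ``"per-bird"``
    counts single-bird dose-days against actual chicken-days at risk
    (Σ birds × 7), a sensitivity variant that differs once mortality thins
    the flock.
    """
    from .ledger import cumulative_mortality as _cum_mort

    events, excluded = _iter_quantifiable(flock, products)
    sold_kg = kg_sold(flock, curve)

    mg_treat: dict[str, float] = {}
    mg_total: dict[str, float] = {}
    dose_days: dict[str, float] = {}

    for week, event, product in events:
        b = biomass(flock, week, curve)
        if b <= 0:
            raise ValidationError(
                f"flock {flock.flock_id!r}: medication recorded in week {week} "
                "with zero biomass"
            )
        masses = event_aai_mass(event, product)
        for name, mg in masses.items():
            mg_treat[name] = mg_treat.get(name, 0.0) + mg / b
            mg_total[name] = mg_total.get(name, 0.0) + mg
        if ti_denominator == "biomass":
            _, per_aai = event_doses(event, product, b, intake)
        else:  # single-bird dose-days
            per_bird_kg = curve.weight(week)
            _, per_aai = event_doses(event, product, per_bird_kg, intake)
        for name, dd in per_aai.items():
            dose_days[name] = dose_days.get(name, 0.0) + dd

    if ti_denominator == "biomass":
        denom_days = 7.0 * flock.n_weeks
    else:
        denom_days = 7.0 * sum(w.birds_present for w in flock.weeks)
    ti_by_aai = {name: 1000.0 * dd / denom_days for name, dd in dose_days.items()}

    names = sorted(set(mg_treat) | set(ti_by_aai))
    per_aai_metrics = {
        name: PerAaiMetrics(
            mg_per_kg_at_treatment=mg_treat.get(name, 0.0),
            mg_per_kg_sold=(
                mg_total.get(name, 0.0) / sold_kg if sold_kg > 0 else None
            ),
            treatment_incidence=ti_by_aai.get(name, 0.0),
        )
        for name in names
    }
    return FlockMetrics(
        flock_id=flock.flock_id,
        farm_id=flock.farm_id,
        mg_per_kg_at_treatment=sum(mg_treat.values()),
        mg_per_kg_sold=(sum(mg_total.values()) / sold_kg if sold_kg > 0 else None),
        treatment_incidence=sum(ti_by_aai.values()),
        per_aai=per_aai_metrics,
        excluded_events=excluded,
        cumulative_mortality=_cum_mort(flock),
        n_weeks=flock.n_weeks,
    )


def top_quartile_share(values: Sequence[float]) -> float:
    """Share of the total held by the highest ⌈n/4⌉ flocks."""
    arr = np.sort(np.asarray(values, dtype=float))[::-1]
    if arr.size == 0:
        raise ValidationError("top_quartile_share of empty input")
    total = arr.sum()
    if total == 0:
        return 0.0
    k = int(np.ceil(arr.size / 4))
    return float(arr[:k].sum() / total)


_METRICS = ("mg_per_kg_at_treatment", "mg_per_kg_sold", "treatment_incidence")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level distribution summaries of the three metrics.

    ``overall`` has one row per metric (n, mean, SEM, median, quartiles,
    top-quartile share); ``per_aai`` and ``per_class`` carry mean ± SEM of
    each metric by active ingredient and by antimicrobial class, where a
    flock that never used an AAI contributes zero (so per-AAI means add up
    to the cohort mean for each metric).
    """

    overall: pd.DataFrame
    per_aai: pd.DataFrame
    per_class: pd.DataFrame
    n_flocks: int
    n_flocks_sold: int


def _summary_row(metric: str, values: np.ndarray) -> dict:
    n = values.size
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])  # linear (type-7)
    return {
        "metric": metric,
        "n": n,
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
        "top_quartile_share": top_quartile_share(values),
    }


def cohort_summary(
    flock_metrics: Sequence[FlockMetrics],
    aai_classes: Mapping[str, str] | None = None,
) -> CohortSummary:
    """Summarise per-flock metrics across a cohort.

    Flocks lacking ``mg_per_kg_sold`` (100% mortality) are omitted from that
    metric's statistics only.  ``aai_classes`` maps AAI name to its
    antimicrobial class for the per-class table; unknown AAIs group under
    ``unclassified``.
    """
    if not flock_metrics:
        raise ValidationError("cohort_summary of empty input")
    aai_classes = aai_classes or {}

    overall_rows = []
    for metric in _METRICS:
        values = np.asarray(
            [
                getattr(m, metric)
                for m in flock_metrics
                if getattr(m, metric) is not None
            ],
            dtype=float,
        )
        if values.size:
            overall_rows.append(_summary_row(metric, values))

    all_aais = sorted({name for m in flock_metrics for name in m.per_aai})
    per_aai_rows = []
    for name in all_aais:
        row: dict = {
            "aai_name": name,
            "antimicrobial_class": aai_classes.get(name, "unclassified"),
        }
        for metric in _METRICS:
            values = []
            for m in flock_metrics:
                pa = m.per_aai.get(name, PerAaiMetrics())
                v = getattr(pa, metric)
                if metric == "mg_per_kg_sold":
                    if m.mg_per_kg_sold is None:
                        continue  # flock excluded from this metric entirely
                    v = v if v is not None else 0.0
                values.append(v)
            arr = np.asarray(values, dtype=float)
            row[f"{metric}_mean"] = float(arr.mean()) if arr.size else float("nan")
            row[f"{metric}_sem"] = (
                float(arr.std(ddof=1) / np.sqrt(arr.size))
                if arr.size > 1
                else float("nan")
            )
        per_aai_rows.append(row)
    per_aai = pd.DataFrame(per_aai_rows)

    per_class_rows = []
    if all_aais:
        classes = sorted(
            {aai_classes.get(name, "unclassified") for name in all_aais}
        )
        for cls in classes:
            members = [n for n in all_aais if aai_classes.get(n, "unclassified") == cls]
            row = {"antimicrobial_class": cls, "n_aais": len(members)}
            for metric in _METRICS:
                values = []
                for m in flock_metrics:
                    if metric == "mg_per_kg_sold" and m.mg_per_kg_sold is None:
                        continue
                    v = 0.0
                    for name in members:
                        pa = m.per_aai.get(name)
                        if pa is None:
                            continue
                        vv = getattr(pa, metric)
                        v += vv if vv is not None else 0.0
                    values.append(v)
                arr = np.asarray(values, dtype=float)
                row[f"{metric}_mean"] = float(arr.mean()) if arr.size else float("nan")
                row[f"{metric}_sem"] = (
                    float(arr.std(ddof=1) / np.sqrt(arr.size))
                    if arr.size > 1
                    else float("nan")
                )
            per_class_rows.append(row)
    per_class = pd.DataFrame(per_class_rows)

    return CohortSummary(
        overall=pd.DataFrame(overall_rows),
        per_aai=per_aai,
        per_class=per_class,
        n_flocks=len(flock_metrics),
        n_flocks_sold=sum(m.mg_per_kg_sold is not None for m in flock_metrics),
    )


def metrics_frame(flock_metrics: Sequence[FlockMetrics]) -> pd.DataFrame:
    """One row per flock with the three metrics and bookkeeping columns."""
    return pd.DataFrame(
        [
            {
                "flock_id": m.flock_id,
                "farm_id": m.farm_id,
                "mg_per_kg_at_treatment": m.mg_per_kg_at_treatment,
                "mg_per_kg_sold": m.mg_per_kg_sold,
                "treatment_incidence": m.treatment_incidence,
                "cumulative_mortality": m.cumulative_mortality,
                "n_weeks": m.n_weeks,
                "excluded_events": m.excluded_events,
            }
            for m in flock_metrics
        ]
    )
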