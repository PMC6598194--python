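"""Synthetic product catalogs and flock cohorts with known ground truth.

The study population this generator emulates is a cohort of small-scale
chicken farms raising slow-growing meat birds over 16–20-week cycles, with
heavy early ("brooding"-period) antimicrobial use that declines with flock
age.  Defaults are anchored to the cohort structure reported for the Mekong
Delta system this package was built around: restock size median 300 birds
(IQR 200–495), cycle length median 18 weeks (IQR 16–20), cumulative
mortality median 14.1% (IQR 6.8–29.2) with ~4% of flocks losing every bird,
weekly use probability 0.76 in week 1, 0.41 in week 2 and 0.02 by week 21,
and a product catalog in which ~60% of antimicrobial products combine two
active ingredients.

Every random draw flows from one seed, and every generated event records
its ground truth (dosing-error multiplier, treated days, per-AAI masses),
so pipeline outputs can be checked against closed-form identities: with a
unit multiplier, a flock's treatment incidence equals 1000 × its true
medicated-day fraction exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    AAI,
    Formulation,
    Ingredient,
    IntakeModel,
    MedicineType,
    Product,
    Route,
    is_quantifiable,
    product_daily_dose,
)
from .errors import ValidationError
from .ledger import FlockLedger, GrowthCurve, MedicationEvent, WeekEntry, default_growth_curve
from .reference import DEFAULT_AAI_POOL, default_classification

__all__ = [
    "CatalogConfig",
    "ScenarioConfig",
    "generate_catalog",
    "generate_cohort",
    "simulate_use_grid",
    "use_probability_curve",
    "write_bundle",
    "GroundTruth",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class CatalogConfig:
    """Shape of the synthetic product catalog.

    Fractions mirror the descriptive composition of the emulated catalog:
    ~6.8% human medicines; among animal medicines, oral-water dominates;
    ~91% powders; ingredient counts 1/2/4 at ~40/60/0.4%; a quarter of
    products mix AAIs with vitamins or other substances.
    """

    n_products: int = 236
    frac_human: float = 0.068
    route_probs: tuple[float, float, float] = (0.886, 0.089, 0.025)  # water/feed/inj
    frac_powder: float = 0.911
    ingredient_count_probs: tuple[float, float, float] = (0.399, 0.597, 0.004)
    frac_other_substances: float = 0.254
    aai_pool: tuple[str, ...] = DEFAULT_AAI_POOL
    # concentration (mg per g or ml): log-uniform
    concentration_range: tuple[float, float] = (20.0, 500.0)
    # therapeutic mix rate: lognormal, median in g/l (water) or g/kg (feed)
    mix_rate_median_water: float = 1.0
    mix_rate_median_feed: float = 2.0
    mix_rate_log_sigma: float = 0.6
    prophylactic_strength: float = 0.5  # label prophylaxis = half strength
    frac_with_dddvet: float = 0.7  # share of AAIs given a synthetic EU value

    def __post_init__(self) -> None:
        if self.n_products < 1:
            raise ValidationError("n_products must be >= 1")
        for name, probs in (
            ("route_probs", self.route_probs),
            ("ingredient_count_probs", self.ingredient_count_probs),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be non-negative and sum to 1")
        for frac in (self.frac_human, self.frac_powder, self.frac_other_substances):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioConfig:
    """Cohort-level scenario: farms, flocks, mortality, medication, dosing."""

    n_farms: int = 102
    # P(a farm contributes 1..5 complete cycles)
    flocks_per_farm_probs: tuple[float, ...] = (0.325, 0.392, 0.186, 0.078, 0.019)
    # restock size ~ LogNormal truncated to [100, 1530]; location solved so
    # the TRUNCATED median is 300 (truncating at 100 birds shifts it up),
    # sigma from the target IQR ratio 495/200
    restock_log_mean: float = math.log(287.18)
    restock_log_sigma: float = 0.672
    restock_bounds: tuple[int, int] = (100, 1530)
    # cycle length in weeks ~ round(Normal), clamped
    cycle_mean: float = 18.0
    cycle_sd: float = 2.97
    cycle_bounds: tuple[int, int] = (10, 22)
    # weekly mortality hazard shared within flock ~ Beta(alpha, beta);
    # Beta(1, 82) gives cumulative mortality median ~0.141 over 18 weeks
    hazard_alpha: float = 1.0
    hazard_beta: float = 82.0
    hazard_scale: float = 1.0  # 0 switches mortality off entirely
    extinction_prob: float = 0.04  # flock loses every bird mid-cycle
    # weekly use probability anchors (production week -> probability),
    # logit-interpolated between anchors and extrapolated beyond the last
    use_prob_anchors: tuple[tuple[int, float], ...] = ((1, 0.76), (2, 0.41), (21, 0.02))
    seasonal_amplitude: float = 0.0  # log-odds amplitude of annual harmonic
    seasonal_period: float = 52.0
    seasonal_phase: float = 0.0
    # events in a medicated week: 1 + Binomial(1, p_second_event)
    p_second_event: float = 0.5
    treated_days_choices: tuple[int, ...] = (3, 4, 5)
    p_excluded_product: float = 0.04  # share of events using injectable/human
    # dosing-error multiplier: "unit" (exactly 1) or "mixture"
    # (prophylactic half-strength w.p. p_prophylactic, else lognormal mean 1)
    dosing_multiplier_mode: str = "mixture"
    p_prophylactic: float = 0.2
    overdose_log_sigma: float = 0.35
    # calendar: restock ISO week uniform over a study window
    study_window_weeks: int = 80
    origin: tuple[int, int] = (2016, 40)  # ISO (year, week) of study start
    growth_curve: GrowthCurve = field(default_factory=default_growth_curve)
    intake: IntakeModel = field(default_factory=IntakeModel)
    catalog: CatalogConfig = field(default_factory=CatalogConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.flocks_per_farm_probs) - 1.0) > 1e-9:
            raise ValidationError("flocks_per_farm_probs must sum to 1")
        if not 0 <= self.extinction_prob <= 1:
            raise ValidationError("extinction_prob must lie in [0, 1]")
        if self.dosing_multiplier_mode not in ("unit", "mixture"):
            raise ValidationError("dosing_multiplier_mode must be unit|mixture")
        for wk, p in self.use_prob_anchors:
            if not (0 < p < 1):
                raise ValidationError("use-probability anchors must lie in (0, 1)")
        if self.cycle_bounds[1] > self.growth_curve.max_week:
            raise ValidationError(
                "growth curve shorter than the longest allowed cycle"
            )

    @property
    def multiplier_mean(self) -> float:
        """Analytic mean of the dosing-error multiplier distribution."""
        if self.dosing_multiplier_mode == "unit":
            return 1.0
        # lognormal component is parameterised to have mean exactly 1
        return self.p_prophylactic * 0.5 + (1.0 - self.p_prophylactic) * 1.0


def use_probability_curve(config: ScenarioConfig, max_week: int) -> np.ndarray:
    """Weekly use probabilities for weeks 1..max_week (logit interpolation).

    Between anchors the log-odds are linear in production week; beyond the
    last anchor the final segment's slope continues, so the probability
    keeps declining smoothly past week 21.
    """
    anchors = sorted(config.use_prob_anchors)
    weeks = np.array([w for w, _ in anchors], dtype=float)
    logits = np.array([_logit(p) for _, p in anchors], dtype=float)
    out = np.empty(max_week, dtype=float)
    for i in range(1, max_week + 1):
        if i <= weeks[0]:
            value = logits[0]
        elif i >= weeks[-1]:
            slope = (logits[-1] - logits[-2]) / (weeks[-1] - weeks[-2])
            value = logits[-1] + slope * (i - weeks[-1])
        else:
            value = float(np.interp(i, weeks, logits))
        out[i - 1] = _expit(value)
    return out


# ---------------------------------------------------------------------------
# catalog generation


def generate_catalog(
    config: ScenarioConfig | CatalogConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, Product], dict[str, AAI], pd.DataFrame, dict[str, float]]:
    """Generate a product catalog with known per-(product, AAI) daily doses.

    Returns ``(products, classification, truth, ddd_reference)`` where
    ``truth`` has one row per (product, AAI) with the exact daily dose
    implied by the generated mix rate and concentration (NaN for excluded
    products), and ``ddd_reference`` is a synthetic EU-style reference built
    by jittering per-AAI mean doses (labelled synthetic; it stands in for a
    reference table that is not shipped with the package).
    """
    cat = config.catalog if isinstance(config, ScenarioConfig) else config
    intake = config.intake if isinstance(config, ScenarioConfig) else IntakeModel()
    rng = np.random.default_rng(rng)
    classification = default_classification()
    pool = [name for name in cat.aai_pool if name in classification]
    if not pool:
        raise ValidationError("empty AAI pool")

    products: dict[str, Product] = {}
    truth_rows: list[dict] = []
    for i in range(cat.n_products):
        pid = f"P{i + 1:04d}"
        human = rng.random() < cat.frac_human
        if human:
            route = Route.ORAL_WATER  # tablets; route is moot, dose excluded
            medicine_type = MedicineType.HUMAN
        else:
            medicine_type = MedicineType.ANIMAL
            routes = (Route.ORAL_WATER, Route.ORAL_FEED, Route.INJECTION)
            route = routes[int(rng.choice(3, p=cat.route_probs))]
        formulation = (
            Formulation.POWDER if rng.random() < cat.frac_powder else Formulation.LIQUID
        )
        n_ing = int(rng.choice([1, 2, 4], p=cat.ingredient_count_probs))
        names = rng.choice(pool, size=n_ing, replace=False)
        lo, hi = cat.concentration_range
        concentrations = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_ing))
        ingredients = tuple(
            Ingredient(aai=classification[str(n)], concentration=float(c))
            for n, c in zip(names, concentrations)
        )
        if medicine_type is MedicineType.HUMAN or route is Route.INJECTION:
            mix = None
        else:
            median = (
                cat.mix_rate_median_water
                if route is Route.ORAL_WATER
                else cat.mix_rate_median_feed
            )
            mix = float(
                np.exp(rng.normal(math.log(median), cat.mix_rate_log_sigma))
            )
        product = Product(
            product_id=pid,
            medicine_type=medicine_type,
            route=route,
            formulation=formulation,
            ingredients=ingredients,
            other_substances=bool(rng.random() < cat.frac_other_substances),
            therapeutic_mix_rate=mix,
            prophylactic_mix_rate=(
                mix * cat.prophylactic_strength if mix is not None else None
            ),
        )
        products[pid] = product
        for ing in ingredients:
            if is_quantifiable(product):
                add = (
                    product_daily_dose(product, intake) * ing.concentration / 1000.0
                )
            else:
                add = float("nan")
            truth_rows.append(
                {
                    "product_id": pid,
                    "aai_name": ing.aai.name,
                    "addvet_mg_per_kg_day": add,
                    "quantifiable": is_quantifiable(product),
                }
            )
    truth = pd.DataFrame(truth_rows)

    # synthetic EU-style daily-dose reference: per-AAI mean, log-jittered
    ddd_reference: dict[str, float] = {}
    quant = truth[truth["quantifiable"]]
    for name, grp in quant.groupby("aai_name"):
        if rng.random() < cat.frac_with_dddvet:
            ddd_reference[str(name)] = float(
                grp["addvet_mg_per_kg_day"].mean()
                * np.exp(rng.normal(0.0, 0.5))
            )
    return products, classification, truth, ddd_reference


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroundTruth:
    """Per-flock and per-event truth recorded at generation time."""

    per_flock: pd.DataFrame  # medicated-day fraction, true dose-days, ...
    per_event: pd.DataFrame  # multiplier, treated days, per-event dose-days
    per_aai_mass_mg: dict[str, float]  # cohort-total true AAI masses


def _draw_restock(config: ScenarioConfig, rng: np.random.Generator) -> int:
    lo, hi = config.restock_bounds
    for _ in range(1000):
        value = int(
            round(np.exp(rng.normal(config.restock_log_mean, config.restock_log_sigma)))
        )
        if lo <= value <= hi:
            return value
    raise ValidationError("restock size distribution rejected 1000 draws")


def _draw_multiplier(config: ScenarioConfig, rng: np.random.Generator) -> float:
    if config.dosing_multiplier_mode == "unit":
        return 1.0
    if rng.random() < config.p_prophylactic:
        return 0.5
    sigma = config.overdose_log_sigma
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))  # mean exactly 1


def generate_cohort(
    config: ScenarioConfig,
    products: Mapping[str, Product],
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, FlockLedger], GroundTruth]:
    """Generate flock ledgers with medication events and ground truth.

    Event amounts are constructed so that a quantifiable event's dose-days
    equal ``multiplier × treated_days`` exactly:
    ``amount = multiplier × daily product dose × biomass × treated_days``.
    Excluded products (injectable / human) receive modest ad-hoc amounts —
    their mass cannot be derived from labels, which is the point.
    """
    rng = np.random.default_rng(rng)
    curve = config.growth_curve
    quantifiable_ids = [p.product_id for p in products.values() if is_quantifiable(p)]
    excluded_ids = [
        p.product_id
        for p in products.values()
        if p.is_antimicrobial and not is_quantifiable(p)
    ]
    if not quantifiable_ids:
        raise ValidationError("catalog has no quantifiable products")

    ledgers: dict[str, FlockLedger] = {}
    flock_rows: list[dict] = []
    event_rows: list[dict] = []
    per_aai_mass: dict[str, float] = {}

    flock_counter = 0
    n_flock_choices = np.arange(1, len(config.flocks_per_farm_probs) + 1)
    for farm_i in range(config.n_farms):
        farm_id = f"F{farm_i + 1:03d}"
        n_cycles = int(rng.choice(n_flock_choices, p=config.flocks_per_farm_probs))
        for _ in range(n_cycles):
            flock_counter += 1
            flock_id = f"{farm_id}C{flock_counter:04d}"
            restocked = _draw_restock(config, rng)
            lo, hi = config.cycle_bounds
            n_weeks = int(np.clip(round(rng.normal(config.cycle_mean, config.cycle_sd)), lo, hi))
            start_index = int(rng.integers(0, config.study_window_weeks))

            hazard = config.hazard_scale * float(
                rng.beta(config.hazard_alpha, config.hazard_beta)
            )
            extinct = rng.random() < config.extinction_prob
            extinct_week = int(rng.integers(2, n_weeks + 1)) if extinct else None

            use_probs = use_probability_curve(config, n_weeks)

            entries: list[WeekEntry] = []
            birds = restocked
            true_dose_days = 0.0
            true_treated_days = 0
            d0 = _dt.date.fromisocalendar(*config.origin, 1)
            for week in range(1, n_weeks + 1):
                iso = (d0 + _dt.timedelta(weeks=start_index + week - 1)).isocalendar()
                if extinct_week is not None and week == extinct_week:
                    deaths = birds
                elif birds > 0:
                    deaths = int(rng.binomial(birds, hazard))
                    if week == n_weeks and extinct_week is None:
                        deaths = min(deaths, birds - 1)  # a sold flock sells >=1
                else:
                    deaths = 0

                events: list[MedicationEvent] = []
                p_use = use_probs[week - 1]
                if config.seasonal_amplitude != 0.0:
                    t = start_index + week - 1
                    p_use = float(
                        _expit(
                            _logit(p_use)
                            + config.seasonal_amplitude
                            * np.sin(
                                2.0 * np.pi * (t - config.seasonal_phase)
                                / config.seasonal_period
                            )
                        )
                    )
                if birds > 0 and rng.random() < p_use:
                    n_events = 1 + int(rng.random() < config.p_second_event)
                    for _e in range(n_events):
                        # a small share of antimicrobial events use excluded
                        # (injectable / human) products, as real records do
                        if excluded_ids and rng.random() < config.p_excluded_product:
                            pid = str(rng.choice(excluded_ids))
                            amount = float(np.round(rng.uniform(5.0, 20.0), 2))
                            events.append(MedicationEvent(pid, amount))
                            event_rows.append(
                                {
                                    "flock_id": flock_id,
                                    "production_week": week,
                                    "product_id": pid,
                                    "amount": amount,
                                    "multiplier": float("nan"),
                                    "treated_days": 0,
                                    "dose_days": 0.0,
                                    "quantifiable": False,
                                }
                            )
                            continue
                        pid = str(rng.choice(quantifiable_ids))
                        product = products[pid]
                        days = int(rng.choice(config.treated_days_choices))
                        multiplier = _draw_multiplier(config, rng)
                        biomass_kg = birds * curve.weight(week)
                        pdd = product_daily_dose(product, config.intake)
                        amount = multiplier * pdd * biomass_kg * days / 1000.0
                        events.append(MedicationEvent(pid, amount))
                        true_dose_days += multiplier * days
                        true_treated_days += days
                        for ing in product.ingredients:
                            mass = amount * ing.concentration
                            per_aai_mass[ing.aai.name] = (
                                per_aai_mass.get(ing.aai.name, 0.0) + mass
                            )
                        event_rows.append(
                            {
                                "flock_id": flock_id,
                                "production_week": week,
                                "product_id": pid,
                                "amount": amount,
                                "multiplier": multiplier,
                                "treated_days": days,
                                "dose_days": multiplier * days,
                                "quantifiable": True,
                            }
                        )

                entries.append(
                    WeekEntry(
                        production_week=week,
                        iso_year=iso.year,
                        iso_week=iso.week,
                        birds_present=birds,
                        deaths=deaths,
                        events=tuple(events),
                    )
                )
                birds -= deaths

            last = entries[-1]
            ledger = FlockLedger(
                flock_id=flock_id,
                farm_id=farm_id,
                restocked=restocked,
                weeks=tuple(entries),
                sold=last.birds_present - last.deaths,
            )
            ledgers[flock_id] = ledger
            flock_rows.append(
                {
                    "flock_id": flock_id,
                    "farm_id": farm_id,
                    "restocked": restocked,
                    "n_weeks": n_weeks,
                    "start_index": start_index,
                    "hazard": hazard,
                    "extinct": bool(extinct),
                    "true_dose_days": true_dose_days,
                    "true_treated_days": true_treated_days,
                    "medicated_day_fraction": true_treated_days / (7.0 * n_weeks),
                    "true_ti": 1000.0 * true_dose_days / (7.0 * n_weeks),
                }
            )

    truth = GroundTruth(
        per_flock=pd.DataFrame(flock_rows),
        per_event=pd.DataFrame(event_rows),
        per_aai_mass_mg=per_aai_mass,
    )
    return ledgers, truth


# ---------------------------------------------------------------------------
# grid-only simulator (for seasonal-model calibration studies)


def simulate_use_grid(
    n_flocks: int,
    rng: np.random.Generator | int | None = None,
    *,
    intercept: float = 1.2,
    age_slope: float = -0.3,
    seasonal_amplitude: float = 0.0,
    n_weeks: int = 18,
    window_weeks: int = 80,
    period: float = 52.0,
) -> pd.DataFrame:
    """Simulate a flock-week use panel directly from a logistic model.

    The data-generating process is exactly the model the seasonal fit
    estimates — log-odds linear in production week plus an annual sine of
    the calendar week — which is what a calibration study needs: under
    ``seasonal_amplitude=0`` the harmonic terms are truly null.
    """
    rng = np.random.default_rng(rng)
    starts = rng.integers(0, window_weeks, size=n_flocks)
    age = np.tile(np.arange(1, n_weeks + 1), n_flocks)
    flock = np.repeat(np.arange(n_flocks), n_weeks)
    t = starts[flock] + age - 1
    logits = (
        intercept
        + age_slope * age
        + seasonal_amplitude * np.sin(2.0 * np.pi * t / period)
    )
    used = (rng.random(logits.size) < _expit(logits)).astype(int)
    return pd.DataFrame(
        {
            "flock_id": np.char.add("S", flock.astype(str)),
            "production_week": age,
            "calendar_index": t,
            "used": used,
        }
    )


# ---------------------------------------------------------------------------
# file emission


def write_bundle(
    outdir: str | Path,
    products: Mapping[str, Product],
    classification: Mapping[str, AAI],
    ledgers: Mapping[str, FlockLedger],
    curve: GrowthCurve,
    truth: GroundTruth | None = None,
    ddd_reference: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write the CSV bundle consumed by the pipeline (plus ground truth).

    Emits ``catalog.csv`` (one row per product-ingredient),
    ``classification.csv``, ``records.csv``, ``events.csv``,
    ``growth_curve.csv`` and, when truth is given, ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cat_rows = []
    for p in products.values():
        base = {
            "product_id": p.product_id,
            "product_name": f"product {p.product_id}",
            "medicine_type": p.medicine_type.value,
            "route": p.route.value,
            "formulation": p.formulation.value,
            "mix_rate_therapeutic": p.therapeutic_mix_rate,
            "mix_rate_prophylactic": p.prophylactic_mix_rate,
            "other_substances": p.other_substances,
        }
        if p.ingredients:
            for ing in p.ingredients:
                cat_rows.append(
                    {
                        **base,
                        "aai_name": ing.aai.name,
                        "concentration_mg_per_unit": ing.concentration,
                    }
                )
        else:
            cat_rows.append(
                {**base, "aai_name": "", "concentration_mg_per_unit": float("nan")}
            )
    paths["catalog"] = outdir / "catalog.csv"
    pd.DataFrame(cat_rows).to_csv(paths["catalog"], index=False)

    cls_rows = [
        {
            "aai_name": a.name,
            "antimicrobial_class": a.antimicrobial_class,
            "who_tier": a.who_tier.value,
            "oie_listed": a.oie_listed,
            "dddvet_eu_mg_per_kg_day": (ddd_reference or {}).get(a.name),
        }
        for a in classification.values()
    ]
    paths["classification"] = outdir / "classification.csv"
    pd.DataFrame(cls_rows).to_csv(paths["classification"], index=False)

    rec_rows, ev_rows = [], []
    for fl in ledgers.values():
        for w in fl.weeks:
            rec_rows.append(
                {
                    "flock_id": fl.flock_id,
                    "farm_id": fl.farm_id,
                    "production_week": w.production_week,
                    "iso_year": w.iso_year,
                    "iso_week": w.iso_week,
                    "birds_present": w.birds_present,
                    "deaths": w.deaths,
                }
            )
            for e in w.events:
                unit = (
                    "ml"
                    if products[e.product_id].formulation is Formulation.LIQUID
                    else "g"
                )
                ev_rows.append(
                    {
                        "flock_id": fl.flock_id,
                        "production_week": w.production_week,
                        "product_id": e.product_id,
                        "amount": e.amount,
                        "unit": unit,
                    }
                )
    paths["records"] = outdir / "records.csv"
    pd.DataFrame(rec_rows).to_csv(paths["records"], index=False)
    paths["events"] = outdir / "events.csv"
    pd.DataFrame(ev_rows).to_csv(paths["events"], index=False)

    paths["growth"] = outdir / "growth_curve.csv"
    pd.DataFrame(
        {
            "week": sorted(curve.week_weights),
            "weight_kg": [curve.week_weights[w] for w in sorted(curve.week_weights)],
        }
    ).to_csv(paths["growth"], index=False)

    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        payload = {
            "per_flock": truth.per_flock.to_dict(orient="records"),
            "per_event": truth.per_event.to_dict(orient="records"),
            "per_aai_mass_mg": truth.per_aai_mass_mg,
        }
        paths["ground_truth"].write_text(json.dumps(payload, indent=1))
    return paths
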