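"""Shared fixtures: a hand-built mini catalog and flock, plus a small
seeded synthetic cohort.  Everything is generated in memory or in tmp
directories — no stored data files."""

from __future__ import annotations

import numpy as np
import pytest

from amuquant.catalog import (
    AAI,
    Formulation,
    Ingredient,
    IntakeModel,
    MedicineType,
    Product,
    Route,
    WhoTier,
)
from amuquant.ledger import (
    FlockLedger,
    GrowthCurve,
    MedicationEvent,
    WeekEntry,
    default_growth_curve,
)
from amuquant.synthgen import CatalogConfig, ScenarioConfig, generate_catalog, generate_cohort


@pytest.fixture(scope="session")
def colistin() -> AAI:
    return AAI("colistin", "polypeptide", WhoTier.CRITICAL_HIGHEST, True)


@pytest.fixture(scope="session")
def oxytet() -> AAI:
    return AAI("oxytetracycline", "tetracycline", WhoTier.OTHER, True)


@pytest.fixture(scope="session")
def water_product(colistin, oxytet) -> Product:
    """Two-AAI oral-water powder, 1 g/l therapeutic mix, 200 mg/g each."""
    return Product(
        product_id="W1",
        medicine_type=MedicineType.ANIMAL,
        route=Route.ORAL_WATER,
        formulation=Formulation.POWDER,
        ingredients=(
            Ingredient(colistin, 200.0),
            Ingredient(oxytet, 200.0),
        ),
        therapeutic_mix_rate=1.0,
    )


@pytest.fixture(scope="session")
def feed_product(oxytet) -> Product:
    """Single-AAI oral-feed powder, 2 g per kg of feed."""
    return Product(
        product_id="D1",
        medicine_type=MedicineType.ANIMAL,
        route=Route.ORAL_FEED,
        formulation=Formulation.POWDER,
        ingredients=(Ingredient(oxytet, 100.0),),
        therapeutic_mix_rate=2.0,
    )


@pytest.fixture(scope="session")
def injectable(colistin) -> Product:
    return Product(
        product_id="I1",
        medicine_type=MedicineType.ANIMAL,
        route=Route.INJECTION,
        formulation=Formulation.LIQUID,
        ingredients=(Ingredient(colistin, 50.0),),
    )


@pytest.fixture(scope="session")
def human_tablet(oxytet) -> Product:
    return Product(
        product_id="H1",
        medicine_type=MedicineType.HUMAN,
        route=Route.ORAL_WATER,
        formulation=Formulation.POWDER,
        ingredients=(Ingredient(oxytet, 500.0),),
    )


@pytest.fixture(scope="session")
def mini_products(water_product, feed_product, injectable, human_tablet):
    return {
        p.product_id: p
        for p in (water_product, feed_product, injectable, human_tablet)
    }


@pytest.fixture(scope="session")
def flat_curve() -> GrowthCurve:
    """Constant 1 kg birds: makes hand arithmetic trivial."""
    return GrowthCurve({w: 1.0 for w in range(1, 25)}, empirical=True)


@pytest.fixture(scope="session")
def growth_curve() -> GrowthCurve:
    return default_growth_curve()


def make_flock(
    flock_id: str = "FL1",
    restocked: int = 300,
    n_weeks: int = 10,
    deaths_by_week: dict[int, int] | None = None,
    events_by_week: dict[int, list[MedicationEvent]] | None = None,
    start: tuple[int, int] = (2017, 2),
) -> FlockLedger:
    """Build a valid ledger from sparse death/event specifications."""
    import datetime as dt

    deaths_by_week = deaths_by_week or {}
    events_by_week = events_by_week or {}
    d0 = dt.date.fromisocalendar(start[0], start[1], 1)
    entries = []
    birds = restocked
    for week in range(1, n_weeks + 1):
        iso = (d0 + dt.timedelta(weeks=week - 1)).isocalendar()
        deaths = deaths_by_week.get(week, 0)
        entries.append(
            WeekEntry(
                production_week=week,
                iso_year=iso.year,
                iso_week=iso.week,
                birds_present=birds,
                deaths=deaths,
                events=tuple(events_by_week.get(week, ())),
            )
        )
        birds -= deaths
    return FlockLedger(
        flock_id=flock_id,
        farm_id="FA1",
        restocked=restocked,
        weeks=tuple(entries),
        sold=birds,
    )


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A compact cohort (~60 flocks) for integration-style tests."""
    return ScenarioConfig(n_farms=30, catalog=CatalogConfig(n_products=60))


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    rng = np.random.default_rng(20_260_923)
    products, classification, truth, ddd = generate_catalog(small_scenario, rng)
    ledgers, ground_truth = generate_cohort(small_scenario, products, rng)
    return {
        "config": small_scenario,
        "products": products,
        "classification": classification,
        "catalog_truth": truth,
        "ddd": ddd,
        "ledgers": ledgers,
        "truth": ground_truth,
    }
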