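"""Flock-level AMU metrics: masses, dose-days, treatment incidence."""

import numpy as np
import pytest

from amuquant.catalog import IntakeModel, product_daily_dose
from amuquant.errors import ValidationError
from amuquant.ledger import GrowthCurve, MedicationEvent, biomass
from amuquant.metrics import (
    cohort_summary,
    compute_flock_metrics,
    event_aai_mass,
    event_doses,
    mg_per_kg_at_treatment,
    mg_per_kg_sold,
    top_quartile_share,
    treatment_incidence,
)

from .conftest import make_flock


class TestEventAaiMass:
    def test_two_aai_product_masses(self, water_product):
        masses = event_aai_mass(MedicationEvent("W1", 10.0), water_product)
        assert masses == {
            "colistin": pytest.approx(2000.0),
            "oxytetracycline": pytest.approx(2000.0),
        }

    def test_mass_conservation_random_events(self, small_cohort):
        rng = np.random.default_rng(7)
        products = [
            p for p in small_cohort["products"].values() if p.is_antimicrobial
        ]
        for _ in range(200):
            product = products[int(rng.integers(len(products)))]
            amount = float(rng.uniform(0.1, 50))
            masses = event_aai_mass(MedicationEvent(product.product_id, amount), product)
            total_conc = sum(i.concentration for i in product.ingredients)
            assert sum(masses.values()) == pytest.approx(amount * total_conc)

    def test_non_antimicrobial_product_empty(self):
        from amuquant.catalog import Formulation, MedicineType, Product, Route

        vitamin = Product(
            product_id="V",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=(),
            therapeutic_mix_rate=1.0,
        )
        assert event_aai_mass(MedicationEvent("V", 5.0), vitamin) == {}


class TestWeightMetrics:
    def test_mg_per_kg_at_treatment_single_event(self, mini_products, flat_curve):
        # 5 g of W1 = 1000 mg colistin + 1000 mg oxytet at 100 kg biomass
        flock = make_flock(
            restocked=100,
            events_by_week={3: [MedicationEvent("W1", 5.0)]},
        )
        assert mg_per_kg_at_treatment(flock, mini_products, flat_curve) == pytest.approx(
            2000.0 / 100.0
        )

    def test_unmedicated_flock_is_zero(self, mini_products, flat_curve):
        assert mg_per_kg_at_treatment(make_flock(), mini_products, flat_curve) == 0.0

    def test_later_treatment_under_growth_gives_smaller_value(self, mini_products):
        growing = GrowthCurve({w: 0.1 * w for w in range(1, 15)})
        early = make_flock(events_by_week={2: [MedicationEvent("W1", 5.0)]})
        late = make_flock(events_by_week={9: [MedicationEvent("W1", 5.0)]})
        assert mg_per_kg_at_treatment(
            late, mini_products, growing
        ) < mg_per_kg_at_treatment(early, mini_products, growing)

    def test_mg_per_kg_sold_hand_value(self, mini_products):
        curve = GrowthCurve({w: 1.4 for w in range(1, 19)}, empirical=True)
        # 258 birds sold at 1.4 kg = 361.2 kg; 90.3 g of W1 = 36,120 mg AAI
        flock = make_flock(
            restocked=300,
            n_weeks=18,
            deaths_by_week={1: 42},
            events_by_week={2: [MedicationEvent("W1", 90.3)]},
        )
        assert mg_per_kg_sold(flock, mini_products, curve) == pytest.approx(
            36120.0 / 361.2
        )

    def test_total_mortality_makes_metric_absent(self, mini_products, flat_curve):
        flock = make_flock(
            restocked=50,
            n_weeks=6,
            deaths_by_week={4: 50},
            events_by_week={2: [MedicationEvent("W1", 1.0)]},
        )
        assert mg_per_kg_sold(flock, mini_products, flat_curve) is None

    def test_zero_use_gives_zero(self, mini_products, flat_curve):
        assert mg_per_kg_sold(make_flock(), mini_products, flat_curve) == 0.0

    def test_medication_after_extinction_is_a_data_error(self, mini_products, flat_curve):
        flock = make_flock(
            restocked=20,
            n_weeks=6,
            deaths_by_week={2: 20},
            events_by_week={4: [MedicationEvent("W1", 1.0)]},
        )
        with pytest.raises(ValidationError):
            mg_per_kg_at_treatment(flock, mini_products, flat_curve)


class TestEventDoses:
    def test_exact_daily_amount_is_one_dose_day_split_two_ways(self, water_product, flat_curve):
        flock = make_flock(restocked=100)
        b = biomass(flock, 3, flat_curve)  # 100 kg
        daily_amount_g = product_daily_dose(water_product) * b / 1000.0
        total, per_aai = event_doses(
            MedicationEvent("W1", daily_amount_g), water_product, b
        )
        assert total == pytest.approx(1.0)
        assert per_aai == {
            "colistin": pytest.approx(0.5),
            "oxytetracycline": pytest.approx(0.5),
        }

    def test_linearity_in_amount(self, water_product):
        total_1, _ = event_doses(MedicationEvent("W1", 10.0), water_product, 50.0)
        total_2, _ = event_doses(MedicationEvent("W1", 5.0), water_product, 50.0)
        assert total_2 == pytest.approx(total_1 / 2)

    def test_four_way_split(self, flat_curve):
        from amuquant.catalog import AAI, Formulation, Ingredient, MedicineType, Product, Route

        quad = Product(
            product_id="Q",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=tuple(
                Ingredient(AAI(f"drug{i}", "sulfonamide"), 100.0) for i in range(4)
            ),
            therapeutic_mix_rate=1.0,
        )
        b = 100.0
        amount = 2.0 * product_daily_dose(quad) * b / 1000.0  # 2 dose-days
        total, per_aai = event_doses(MedicationEvent("Q", amount), quad, b)
        assert total == pytest.approx(2.0)
        assert all(v == pytest.approx(0.5) for v in per_aai.values())

    def test_dose_conservation_random(self, small_cohort):
        rng = np.random.default_rng(11)
        from amuquant.catalog import is_quantifiable

        products = [
            p for p in small_cohort["products"].values() if is_quantifiable(p)
        ]
        for _ in range(100):
            product = products[int(rng.integers(len(products)))]
            amount = float(rng.uniform(0.5, 100))
            b = float(rng.uniform(10, 800))
            total, per_aai = event_doses(MedicationEvent(product.product_id, amount), product, b)
            assert sum(per_aai.values()) == pytest.approx(total, rel=1e-12)


class TestTreatmentIncidence:
    def test_hand_value(self, water_product, mini_products, flat_curve):
        # 3 dose-days in a 10-week (70-day) cycle -> 1000*3/70
        flock = make_flock(
            restocked=100,
            n_weeks=10,
            events_by_week={
                2: [
                    MedicationEvent(
                        "W1", 3.0 * product_daily_dose(water_product) * 100.0 / 1000.0
                    )
                ]
            },
        )
        assert treatment_incidence(flock, mini_products, flat_curve) == pytest.approx(
            1000.0 * 3.0 / 70.0
        )

    def test_no_use_is_zero(self, mini_products, flat_curve):
        assert treatment_incidence(make_flock(), mini_products, flat_curve) == 0.0

    def test_daily_dosing_reaches_1000(self, water_product, mini_products, flat_curve):
        n_weeks = 8
        events = {
            w: [
                MedicationEvent(
                    "W1", 7.0 * product_daily_dose(water_product) * 100.0 / 1000.0
                )
            ]
            for w in range(1, n_weeks + 1)
        }
        flock = make_flock(restocked=100, n_weeks=n_weeks, events_by_week=events)
        assert treatment_incidence(flock, mini_products, flat_curve) == pytest.approx(
            1000.0
        )

    def test_excluded_events_counted_not_dosed(self, mini_products, flat_curve):
        flock = make_flock(
            restocked=100,
            events_by_week={
                2: [MedicationEvent("I1", 5.0), MedicationEvent("H1", 2.0)]
            },
        )
        fm = compute_flock_metrics(flock, mini_products, flat_curve)
        assert fm.excluded_events == 2
        assert fm.treatment_incidence == 0.0
        assert fm.mg_per_kg_at_treatment == 0.0

    def test_per_bird_denominator_matches_biomass_without_mortality(
        self, mini_products, flat_curve
    ):
        flock = make_flock(
            restocked=100,
            events_by_week={3: [MedicationEvent("W1", 4.0)]},
        )
        ti_biomass = treatment_incidence(flock, mini_products, flat_curve)
        ti_bird = treatment_incidence(
            flock, mini_products, flat_curve, ti_denominator="per-bird"
        )
        assert ti_bird == pytest.approx(ti_biomass)


class TestAdditivity:
    def test_per_aai_components_sum_to_totals(self, small_cohort):
        config = small_cohort["config"]
        for flock in list(small_cohort["ledgers"].values())[:40]:
            fm = compute_flock_metrics(
                flock, small_cohort["products"], config.growth_curve, config.intake
            )
            assert fm.mg_per_kg_at_treatment == pytest.approx(
                sum(p.mg_per_kg_at_treatment for p in fm.per_aai.values())
            )
            assert fm.treatment_incidence == pytest.approx(
                sum(p.treatment_incidence for p in fm.per_aai.values())
            )
            if fm.mg_per_kg_sold is not None:
                assert fm.mg_per_kg_sold == pytest.approx(
                    sum(p.mg_per_kg_sold for p in fm.per_aai.values())
                )


class TestCohortSummary:
    def _fm(self, flock_id, treat, sold, ti):
        from amuquant.metrics import FlockMetrics

        return FlockMetrics(
            flock_id=flock_id,
            farm_id="A",
            mg_per_kg_at_treatment=treat,
            mg_per_kg_sold=sold,
            treatment_incidence=ti,
            per_aai={},
            excluded_events=0,
            cumulative_mortality=0.1,
            n_weeks=18,
        )

    def test_top_quartile_share_rules(self):
        assert top_quartile_share([5.0, 5.0, 5.0, 5.0]) == pytest.approx(0.25)
        assert top_quartile_share([0.0, 0.0, 0.0, 100.0]) == pytest.approx(1.0)
        assert top_quartile_share([1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.4)

    def test_summary_hand_values(self):
        metrics = [self._fm(f"f{i}", v, v, v) for i, v in enumerate([1.0, 2.0, 3.0, 4.0])]
        summary = cohort_summary(metrics)
        row = summary.overall.set_index("metric").loc["mg_per_kg_at_treatment"]
        assert row["mean"] == pytest.approx(2.5)
        assert row["median"] == pytest.approx(2.5)
        assert row["top_quartile_share"] == pytest.approx(0.4)
        # SEM = sd/sqrt(n) with sample sd
        assert row["sem"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2.0)
        # type-7 quartiles
        assert row["q25"] == pytest.approx(1.75)
        assert row["q75"] == pytest.approx(3.25)

    def test_unsold_flocks_excluded_from_sold_metric_only(self):
        metrics = [
            self._fm("a", 1.0, 10.0, 5.0),
            self._fm("b", 2.0, None, 6.0),
            self._fm("c", 3.0, 30.0, 7.0),
        ]
        summary = cohort_summary(metrics)
        table = summary.overall.set_index("metric")
        assert table.loc["mg_per_kg_sold", "n"] == 2
        assert table.loc["mg_per_kg_at_treatment", "n"] == 3
        assert summary.n_flocks_sold == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cohort_summary([])


class TestStructuralProperties:
    def test_ordering_at_treatment_geq_sold_without_mortality(self, mini_products):
        """With zero mortality and a monotone curve, the at-treatment
        denominator never exceeds the final biomass."""
        growing = GrowthCurve({w: 0.08 * w for w in range(1, 20)})
        rng = np.random.default_rng(3)
        for _ in range(50):
            events = {
                int(w): [MedicationEvent("W1", float(rng.uniform(0.5, 20)))]
                for w in rng.choice(np.arange(1, 13), size=3, replace=False)
            }
            flock = make_flock(restocked=200, n_weeks=12, events_by_week=events)
            treat = mg_per_kg_at_treatment(flock, mini_products, growing)
            sold = mg_per_kg_sold(flock, mini_products, growing)
            assert treat >= sold

    def test_late_mortality_raises_sold_metric_only(self, mini_products, flat_curve):
        events = {2: [MedicationEvent("W1", 10.0)]}
        baseline = make_flock(restocked=100, n_weeks=10, events_by_week=events)
        lossy = make_flock(
            restocked=100, n_weeks=10, events_by_week=events, deaths_by_week={8: 40}
        )
        assert mg_per_kg_at_treatment(
            lossy, mini_products, flat_curve
        ) == pytest.approx(mg_per_kg_at_treatment(baseline, mini_products, flat_curve))
        assert mg_per_kg_sold(lossy, mini_products, flat_curve) > mg_per_kg_sold(
            baseline, mini_products, flat_curve
        )
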