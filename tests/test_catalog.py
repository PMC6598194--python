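"""Daily-dose derivation and product classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amuquant.catalog import (
    AAI,
    AddVetValue,
    Formulation,
    Ingredient,
    IntakeModel,
    MedicineType,
    Product,
    Route,
    WhoTier,
    addvet_for,
    addvet_table,
    classify_products,
    product_daily_dose,
)
from amuquant.errors import ExcludedProductError, ValidationError


class TestProductDailyDose:
    def test_oral_water_dose_is_mix_rate_times_water_intake(self, water_product):
        # 1 g/l x 0.225 l/kg/day = 225 mg product per kg per day
        assert product_daily_dose(water_product) == pytest.approx(225.0)

    def test_oral_feed_dose_is_mix_rate_times_feed_intake(self, feed_product):
        # 2 g/kg feed (= 2 mg/g) x 63.4 g feed/kg/day = 126.8 mg/kg/day
        assert product_daily_dose(feed_product) == pytest.approx(126.8)

    def test_injectable_is_excluded_not_invalid(self, injectable):
        with pytest.raises(ExcludedProductError):
            product_daily_dose(injectable)

    def test_human_medicine_is_excluded(self, human_tablet):
        with pytest.raises(ExcludedProductError):
            product_daily_dose(human_tablet)

    def test_intake_override_scales_dose(self, water_product):
        doubled = IntakeModel(water_l_per_kg_day=0.45)
        assert product_daily_dose(water_product, doubled) == pytest.approx(450.0)


class TestAddvetFor:
    def test_concentration_scales_product_dose(self, water_product):
        ing = water_product.ingredients[0]  # 200 mg/g
        assert addvet_for(water_product, ing) == pytest.approx(225.0 * 0.2)

    def test_pure_ingredient_equals_product_dose(self, colistin):
        pure = Product(
            product_id="PURE",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=(Ingredient(colistin, 1000.0),),
            therapeutic_mix_rate=1.5,
        )
        assert addvet_for(pure, pure.ingredients[0]) == pytest.approx(
            product_daily_dose(pure)
        )

    def test_zero_concentration_rejected_at_type_level(self, colistin):
        with pytest.raises(ValidationError):
            Ingredient(colistin, 0.0)

    def test_foreign_ingredient_rejected(self, water_product, colistin):
        stranger = Ingredient(colistin, 123.0)
        with pytest.raises(ValidationError):
            addvet_for(water_product, stranger)

    @given(factor=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_doubling_mix_rate_doubles_every_dose(self, colistin, factor):
        base = Product(
            product_id="B",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=(Ingredient(colistin, 150.0),),
            therapeutic_mix_rate=1.0,
        )
        scaled = Product(
            product_id="B2",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=(Ingredient(colistin, 150.0),),
            therapeutic_mix_rate=factor,
        )
        assert product_daily_dose(scaled) == pytest.approx(
            factor * product_daily_dose(base)
        )
        assert addvet_for(scaled, scaled.ingredients[0]) == pytest.approx(
            factor * addvet_for(base, base.ingredients[0])
        )

    def test_carrier_independence(self, colistin):
        """Water and feed products delivering the same mg product/kg/day
        yield identical per-AAI doses."""
        intake = IntakeModel()
        water = Product(
            product_id="CW",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=(Ingredient(colistin, 80.0),),
            therapeutic_mix_rate=1.0,  # 225 mg/kg/day
        )
        feed = Product(
            product_id="CF",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_FEED,
            formulation=Formulation.POWDER,
            ingredients=(Ingredient(colistin, 80.0),),
            therapeutic_mix_rate=225.0 / intake.feed_g_per_kg_day,
        )
        assert addvet_for(water, water.ingredients[0], intake) == pytest.approx(
            addvet_for(feed, feed.ingredients[0], intake)
        )


class TestAddvetTable:
    def _product(self, aai, mix, pid, route=Route.ORAL_WATER, conc=1000.0, **kw):
        return Product(
            product_id=pid,
            medicine_type=kw.get("medicine_type", MedicineType.ANIMAL),
            route=route,
            formulation=Formulation.POWDER,
            ingredients=(Ingredient(aai, conc),),
            therapeutic_mix_rate=mix,
        )

    def test_mean_and_population_cv(self, colistin):
        # two products delivering 10 and 30 mg/kg/day: mean 20,
        # population sd 10, CV 50%... with sd over n: sqrt(((10)^2+(10)^2)/2)=10
        p1 = self._product(colistin, 10 / 225.0, "A")
        p2 = self._product(colistin, 30 / 225.0, "B")
        (value,) = addvet_table([p1, p2])
        assert value.mean_add_mg_per_kg_day == pytest.approx(20.0)
        assert value.cv_percent == pytest.approx(50.0)
        assert value.n_products == 2

    def test_sample_cv_convention_is_configurable(self, colistin):
        p1 = self._product(colistin, 10 / 225.0, "A")
        p2 = self._product(colistin, 30 / 225.0, "B")
        (value,) = addvet_table([p1, p2], cv_ddof=1)
        # sample sd = 10*sqrt(2), CV = 50*sqrt(2) ~ 70.71%
        assert value.cv_percent == pytest.approx(50.0 * math.sqrt(2))

    def test_single_product_cv_zero(self, colistin):
        (value,) = addvet_table([self._product(colistin, 1.0, "A")])
        assert value.cv_percent == pytest.approx(0.0)

    def test_injectable_only_aai_reported_without_mean(self, injectable):
        (value,) = addvet_table([injectable])
        assert value.n_products == 0
        assert value.mean_add_mg_per_kg_day is None

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValidationError):
            addvet_table([])

    def test_ddd_reference_joined(self, colistin):
        (value,) = addvet_table(
            [self._product(colistin, 1.0, "A")], ddd_reference={"colistin": 7.5}
        )
        assert value.ddd_vet_eu == pytest.approx(7.5)

    def test_mean_matches_bruteforce_on_random_catalogs(self):
        """Table means must equal the brute-force per-AAI average."""
        rng = np.random.default_rng(42)
        names = ["a_drug", "b_drug", "c_drug"]
        for _ in range(20):
            products = []
            expected: dict[str, list[float]] = {}
            for i in range(int(rng.integers(1, 8))):
                chosen = rng.choice(names, size=int(rng.integers(1, 3)), replace=False)
                mix = float(rng.uniform(0.2, 5.0))
                concs = rng.uniform(50, 900, size=len(chosen))
                products.append(
                    Product(
                        product_id=f"R{i}",
                        medicine_type=MedicineType.ANIMAL,
                        route=Route.ORAL_WATER,
                        formulation=Formulation.POWDER,
                        ingredients=tuple(
                            Ingredient(AAI(str(n)), float(c))
                            for n, c in zip(chosen, concs)
                        ),
                        therapeutic_mix_rate=mix,
                    )
                )
                for n, c in zip(chosen, concs):
                    expected.setdefault(str(n), []).append(mix * 225.0 * c / 1000.0)
            table = {v.aai_name: v for v in addvet_table(products)}
            assert set(table) == set(expected)
            for name, values in expected.items():
                assert table[name].mean_add_mg_per_kg_day == pytest.approx(
                    sum(values) / len(values)
                )
                assert table[name].n_products == len(values)


class TestClassifyProducts:
    def test_highest_priority_share(self, water_product, feed_product, injectable, human_tablet):
        # colistin (highest) appears in water_product and injectable: 2 of 4
        df = classify_products([water_product, feed_product, injectable, human_tablet])
        row = df[
            (df.category == "who_tier_highest")
            & (df.subcategory == WhoTier.CRITICAL_HIGHEST.value)
        ].iloc[0]
        assert row.n_products == 2
        assert row.percent == pytest.approx(50.0)

    def test_combination_product_counted_once_in_two_aai_row(self, water_product):
        df = classify_products([water_product])
        two = df[(df.category == "n_aais") & (df.subcategory == "2")].iloc[0]
        assert two.n_products == 1
        one = df[(df.category == "n_aais") & (df.subcategory == "1")].iloc[0]
        assert one.n_products == 0

    def test_empty_antimicrobial_subset_yields_zero_summary(self):
        vitamin = Product(
            product_id="V1",
            medicine_type=MedicineType.ANIMAL,
            route=Route.ORAL_WATER,
            formulation=Formulation.POWDER,
            ingredients=(),
            therapeutic_mix_rate=1.0,
        )
        df = classify_products([vitamin])
        assert (df.n_products == 0).all()
        assert (df.percent == 0).all()


class TestTypeInvariants:
    def test_aai_requires_canonical_lowercase(self):
        with pytest.raises(ValidationError):
            AAI("Colistin")

    def test_aai_rejects_unknown_class(self):
        with pytest.raises(ValidationError):
            AAI("newdrug", "carbapenem")

    def test_product_ingredient_count_closed(self, colistin, oxytet):
        aais = [AAI(f"drug{i}", "sulfonamide") for i in range(3)]
        with pytest.raises(ValidationError):
            Product(
                product_id="X",
                medicine_type=MedicineType.ANIMAL,
                route=Route.ORAL_WATER,
                formulation=Formulation.POWDER,
                ingredients=tuple(Ingredient(a, 100.0) for a in aais),
                therapeutic_mix_rate=1.0,
            )

    def test_oral_product_requires_mix_rate(self, colistin):
        with pytest.raises(ValidationError):
            Product(
                product_id="X",
                medicine_type=MedicineType.ANIMAL,
                route=Route.ORAL_WATER,
                formulation=Formulation.POWDER,
                ingredients=(Ingredient(colistin, 100.0),),
            )

    def test_combination_tier_is_highest_among_ingredients(self, water_product):
        assert water_product.who_tier is WhoTier.CRITICAL_HIGHEST
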