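"""Medicinal products, active ingredients and animal daily doses.

A commercial product is described by its administration route, formulation
and per-ingredient antimicrobial active ingredient (AAI) concentrations,
together with the label mixing instruction (grams or millilitres of product
per litre of drinking water, or per kilogram of feed).  Combining the mixing
instruction with standardised daily water/feed intake per kilogram of live
chicken yields, for each AAI, the animal daily dose: the milligrams of that
AAI delivered to one kilogram of chicken in one day of therapeutic
treatment (denoted ADDvetVN for the Vietnamese chicken catalog this package
was built around).

Only oral veterinary products are quantifiable: the number of birds reached
by an injection is unknown, and human tablets carry no flock-level mixing
guideline.  Those products are modelled, classified and counted, but dose
derivation raises :class:`~amuquant.errors.ExcludedProductError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ExcludedProductError, ValidationError

__all__ = [
    "WhoTier",
    "Route",
    "Formulation",
    "MedicineType",
    "AAI",
    "Ingredient",
    "Product",
    "IntakeModel",
    "AddVetValue",
    "product_daily_dose",
    "addvet_for",
    "addvet_table",
    "classify_products",
    "read_catalog",
    "read_classification",
    "is_quantifiable",
]


class MedicineType(str, Enum):
    ANIMAL = "animal"
    HUMAN = "human"


class Route(str, Enum):
    ORAL_WATER = "oral_water"
    ORAL_FEED = "oral_feed"
    INJECTION = "injection"


class Formulation(str, Enum):
    POWDER = "powder"
    LIQUID = "liquid"


ANTIMICROBIAL_CLASSES = frozenset(
    {
        "aminoglycoside",
        "amphenicol",
        "cephalosporin_1_2",
        "diaminopyrimidine",
        "lincosamide",
        "macrolide",
        "penicillin",
        "pleuromutilin",
        "polypeptide",
        "quinolone",
        "sulfonamide",
        "tetracycline",
        "unclassified",
    }
)


class WhoTier(str, Enum):
    """WHO ranking of antimicrobial classes by importance to human medicine."""

    CRITICAL_HIGHEST = "critically_important_highest_priority"
    CRITICAL_HIGH = "critically_important_high_priority"
    OTHER = "other"
    UNCLASSIFIED = "unclassified"


#: Ordering used when a combination product is assigned the highest tier
#: among its ingredients ("contained at least one AAI of critical importance").
_TIER_RANK = {
    WhoTier.CRITICAL_HIGHEST: 3,
    WhoTier.CRITICAL_HIGH: 2,
    WhoTier.OTHER: 1,
    WhoTier.UNCLASSIFIED: 0,
}


@dataclass(frozen=True)
class AAI:
    """An antimicrobial active ingredient with its classification."""

    name: str
    antimicrobial_class: str = "unclassified"
    who_tier: WhoTier = WhoTier.UNCLASSIFIED
    oie_listed: bool = False

    def __post_init__(self) -> None:
        if not self.name or self.name != self.name.strip().lower():
            raise ValidationError(
                f"AAI name must be canonical lowercase, got {self.name!r}"
            )
        if self.antimicrobial_class not in ANTIMICROBIAL_CLASSES:
            raise ValidationError(
                f"unknown antimicrobial class {self.antimicrobial_class!r} "
                f"for AAI {self.name!r}"
            )


@dataclass(frozen=True)
class Ingredient:
    """One AAI inside a product, at a stated concentration.

    ``concentration`` is mg of AAI per gram of product for powders and mg per
    millilitre for liquids; the arithmetic is identical for both.
    """

    aai: AAI
    concentration: float  # mg per g (powder) or per ml (liquid)

    def __post_init__(self) -> None:
        if not (0 < self.concentration <= 1000):
            raise ValidationError(
                f"concentration for {self.aai.name!r} must be in (0, 1000] "
                f"mg per unit, got {self.concentration}"
            )


@dataclass(frozen=True)
class Product:
    """A commercial medicinal product as described on its package.

    ``therapeutic_mix_rate`` is g (powder) or ml (liquid) of product per
    litre of drinking water for ``oral_water`` routes, per kilogram of feed
    for ``oral_feed``.  The optional prophylactic rate (labels typically
    halve the strength) is retained for the dosing-error simulator and is
    never used in dose derivation.
    """

    product_id: str
    medicine_type: MedicineType
    route: Route
    formulation: Formulation
    ingredients: tuple[Ingredient, ...] = ()
    other_substances: bool = False
    therapeutic_mix_rate: float | None = None
    prophylactic_mix_rate: float | None = None

    def __post_init__(self) -> None:
        n = len(self.ingredients)
        if n not in (0, 1, 2, 4):
            raise ValidationError(
                f"product {self.product_id!r}: ingredient count must be "
                f"0, 1, 2 or 4, got {n}"
            )
        names = [ing.aai.name for ing in self.ingredients]
        if len(set(names)) != n:
            raise ValidationError(
                f"product {self.product_id!r}: duplicate AAI in ingredients"
            )
        oral = self.route in (Route.ORAL_WATER, Route.ORAL_FEED)
        quantifiable = oral and self.medicine_type is MedicineType.ANIMAL
        if quantifiable and self.is_antimicrobial:
            if self.therapeutic_mix_rate is None:
                raise ValidationError(
                    f"product {self.product_id!r}: oral animal medicine "
                    "requires a therapeutic mix rate"
                )
        for rate, label in (
            (self.therapeutic_mix_rate, "therapeutic"),
            (self.prophylactic_mix_rate, "prophylactic"),
        ):
            if rate is not None and not (rate > 0 and math.isfinite(rate)):
                raise ValidationError(
                    f"product {self.product_id!r}: {label} mix rate must be "
                    f"positive and finite, got {rate}"
                )

    @property
    def is_antimicrobial(self) -> bool:
        return len(self.ingredients) > 0

    @property
    def who_tier(self) -> WhoTier:
        """Highest WHO tier among the product's ingredients."""
        if not self.ingredients:
            return WhoTier.UNCLASSIFIED
        return max(
            (ing.aai.who_tier for ing in self.ingredients),
            key=_TIER_RANK.__getitem__,
        )


@dataclass(frozen=True)
class IntakeModel:
    """Standardised daily water and feed intake per kg of live chicken.

    Defaults are the published intake rates for meat-type pullets at 32 °C
    (0.225 l water per kg per day) and native layer pullets (63.4 g feed per
    kg per day); both are treated as age-constant.
    """

    water_l_per_kg_day: float = 0.225
    feed_g_per_kg_day: float = 63.4

    def __post_init__(self) -> None:
        if self.water_l_per_kg_day <= 0 or self.feed_g_per_kg_day <= 0:
            raise ValidationError("intake rates must be strictly positive")


@dataclass(frozen=True)
class AddVetValue:
    """Per-AAI daily-dose summary across the quantifiable catalog."""

    aai_name: str
    mean_add_mg_per_kg_day: float | None
    cv_percent: float | None
    n_products: int
    ddd_vet_eu: float | None = None

    def __post_init__(self) -> None:
        if self.n_products > 0:
            if self.mean_add_mg_per_kg_day is None or self.mean_add_mg_per_kg_day <= 0:
                raise ValidationError(
                    f"{self.aai_name}: mean daily dose must be positive"
                )
            if self.cv_percent is None or self.cv_percent < 0:
                raise ValidationError(f"{self.aai_name}: CV must be >= 0")


def is_quantifiable(product: Product) -> bool:
    """True when label-based dose derivation applies to ``product``."""
    return (
        product.medicine_type is MedicineType.ANIMAL
        and product.route in (Route.ORAL_WATER, Route.ORAL_FEED)
        and product.is_antimicrobial
    )


def product_daily_dose(product: Product, intake: IntakeModel | None = None) -> float:
    """Milligrams of *product* needed to treat 1 kg of chicken for one day.

    The label mixing rate (g or ml of product per litre of water, or per kg
    of feed) is multiplied by the standardised daily intake of the carrier.
    A mix rate of 1 g/l with 0.225 l water per kg per day is 225 mg of
    product per kg per day.

    Raises
    ------
    ExcludedProductError
        For injectables and human medicines, which are outside the
        quantifiable scope.
    ValidationError
        When the therapeutic mix rate is missing on an oral animal product.
    """
    intake = intake or IntakeModel()
    if product.medicine_type is MedicineType.HUMAN or product.route is Route.INJECTION:
        raise ExcludedProductError(
            f"product {product.product_id!r} "
            f"({product.medicine_type.value}, {product.route.value}) is "
            "excluded from quantification"
        )
    if product.therapeutic_mix_rate is None:
        raise ValidationError(
            f"product {product.product_id!r}: no therapeutic mix rate"
        )
    if product.route is Route.ORAL_WATER:
        # (g product / l water) x (l water / kg / day) -> g/kg/day -> mg
        return product.therapeutic_mix_rate * intake.water_l_per_kg_day * 1000.0
    # (g product / kg feed) == (mg product / g feed); x (g feed / kg / day)
    return product.therapeutic_mix_rate * intake.feed_g_per_kg_day


def addvet_for(
    product: Product, ingredient: Ingredient, intake: IntakeModel | None = None
) -> float:
    """Animal daily dose of one AAI in one product, in mg per kg per day.

    This is the product daily dose scaled by the ingredient concentration
    (mg of AAI per g or ml of product).
    """
    if ingredient not in product.ingredients:
        raise ValidationError(
            f"ingredient {ingredient.aai.name!r} does not belong to product "
            f"{product.product_id!r}"
        )
    return product_daily_dose(product, intake) * ingredient.concentration / 1000.0


def addvet_table(
    products: Sequence[Product],
    intake: IntakeModel | None = None,
    ddd_reference: Mapping[str, float] | None = None,
    *,
    cv_ddof: int = 0,
) -> list[AddVetValue]:
    """Per-AAI mean and coefficient of variation of the animal daily dose.

    Each quantifiable product containing an AAI contributes one daily-dose
    value; the mean and CV (population convention by default, ``cv_ddof=1``
    for the sample convention) summarise the spread across products.  AAIs
    appearing only in excluded products (injectables, human medicines) are
    reported with ``n_products=0`` and no mean — they exist in the catalog
    but carry no derivable dose.

    Results are sorted by AAI name for stable output.
    """
    if not products:
        raise ValidationError("empty product catalog")
    per_aai: dict[str, list[float]] = {}
    seen: set[str] = set()
    for product in products:
        for ingredient in product.ingredients:
            seen.add(ingredient.aai.name)
        if not is_quantifiable(product):
            continue
        for ingredient in product.ingredients:
            value = addvet_for(product, ingredient, intake)
            per_aai.setdefault(ingredient.aai.name, []).append(value)

    ddd_reference = ddd_reference or {}
    out: list[AddVetValue] = []
    for name in sorted(seen):
        values = per_aai.get(name, [])
        if values:
            arr = np.asarray(values, dtype=float)
            mean = float(arr.mean())
            sd = float(arr.std(ddof=cv_ddof)) if len(arr) > cv_ddof else 0.0
            cv = 100.0 * sd / mean
            out.append(
                AddVetValue(
                    aai_name=name,
                    mean_add_mg_per_kg_day=mean,
                    cv_percent=cv,
                    n_products=len(values),
                    ddd_vet_eu=ddd_reference.get(name),
                )
            )
        else:
            out.append(
                AddVetValue(
                    aai_name=name,
                    mean_add_mg_per_kg_day=None,
                    cv_percent=None,
                    n_products=0,
                    ddd_vet_eu=ddd_reference.get(name),
                )
            )
    return out


def classify_products(products: Sequence[Product]) -> pd.DataFrame:
    """Frequency summary of the antimicrobial products in a catalog.

    Counts and percentages (relative to the antimicrobial product total) by
    medicine type, composition, number of AAIs, route, formulation and WHO
    importance tier.  A combination product sits in a single ingredient-count
    row and in the highest WHO tier among its ingredients; the ``who_*`` tier
    rows additionally report "at least one ingredient in tier" membership.
    """
    am = [p for p in products if p.is_antimicrobial]
    total = len(am)

    def pct(k: int) -> float:
        return 100.0 * k / total if total else 0.0

    rows: list[dict] = []

    def add(category: str, sub: str, count: int) -> None:
        rows.append(
            {
                "category": category,
                "subcategory": sub,
                "n_products": count,
                "percent": pct(count),
            }
        )

    add("total", "antimicrobial", total)
    for mt in MedicineType:
        add("medicine_type", mt.value, sum(p.medicine_type is mt for p in am))
    add("composition", "aai_only", sum(not p.other_substances for p in am))
    add("composition", "aai_mixed", sum(p.other_substances for p in am))
    for k in (1, 2, 4):
        add("n_aais", str(k), sum(len(p.ingredients) == k for p in am))
    for route in Route:
        add("route", route.value, sum(p.route is route for p in am))
    for form in Formulation:
        add("formulation", form.value, sum(p.formulation is form for p in am))
    # product-level highest tier (each product once)
    for tier in WhoTier:
        add("who_tier_highest", tier.value, sum(p.who_tier is tier for p in am))
    # membership: product has >=1 ingredient in the tier
    for tier in WhoTier:
        add(
            "who_tier_any",
            tier.value,
            sum(
                any(ing.aai.who_tier is tier for ing in p.ingredients) for p in am
            ),
        )
    add(
        "who_critical_any",
        "critically_important",
        sum(
            p.who_tier in (WhoTier.CRITICAL_HIGHEST, WhoTier.CRITICAL_HIGH)
            for p in am
        ),
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_classification(path: str | Path) -> tuple[dict[str, AAI], dict[str, float]]:
    """Read the AAI classification table (and optional EU DDDvet column).

    Expected columns: ``aai_name, antimicrobial_class, who_tier, oie_listed``
    and optionally ``dddvet_eu_mg_per_kg_day``.
    """
    df = pd.read_csv(path)
    required = {"aai_name", "antimicrobial_class", "who_tier", "oie_listed"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"classification table missing columns {sorted(missing)}")
    aais: dict[str, AAI] = {}
    ddd: dict[str, float] = {}
    for row in df.itertuples(index=False):
        name = str(row.aai_name).strip().lower()
        if name in aais:
            raise ValidationError(f"duplicate AAI {name!r} in classification table")
        aais[name] = AAI(
            name=name,
            antimicrobial_class=str(row.antimicrobial_class),
            who_tier=WhoTier(str(row.who_tier)),
            oie_listed=bool(row.oie_listed),
        )
        if "dddvet_eu_mg_per_kg_day" in df.columns:
            value = getattr(row, "dddvet_eu_mg_per_kg_day")
            if value is not None and not pd.isna(value):
                ddd[name] = float(value)
    return aais, ddd


def read_catalog(
    path: str | Path,
    classification: Mapping[str, AAI] | None = None,
) -> dict[str, Product]:
    """Read a product catalog CSV (one row per product-ingredient pair).

    Columns: ``product_id, product_name, medicine_type, route, formulation,
    aai_name, concentration_mg_per_unit, mix_rate_therapeutic,
    mix_rate_prophylactic, other_substances``.  Non-antimicrobial products
    have an empty ``aai_name``.  AAIs absent from the classification table
    are accepted as ``unclassified`` rather than dropped.
    """
    df = pd.read_csv(path)
    required = {
        "product_id",
        "medicine_type",
        "route",
        "formulation",
        "aai_name",
        "concentration_mg_per_unit",
        "mix_rate_therapeutic",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"catalog missing columns {sorted(missing)}")
    classification = classification or {}

    products: dict[str, Product] = {}
    for product_id, group in df.groupby("product_id", sort=True):
        first = group.iloc[0]
        ingredients = []
        for row in group.itertuples(index=False):
            name = row.aai_name
            if name is None or (isinstance(name, float) and math.isnan(name)):
                continue
            name = str(name).strip().lower()
            if not name:
                continue
            aai = classification.get(name, AAI(name=name))
            ingredients.append(
                Ingredient(aai=aai, concentration=float(row.concentration_mg_per_unit))
            )

        def _rate(value) -> float | None:
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return float(value)

        products[str(product_id)] = Product(
            product_id=str(product_id),
            medicine_type=MedicineType(str(first["medicine_type"])),
            route=Route(str(first["route"])),
            formulation=Formulation(str(first["formulation"])),
            ingredients=tuple(ingredients),
            other_substances=bool(first.get("other_substances", False)),
            therapeutic_mix_rate=_rate(first["mix_rate_therapeutic"]),
            prophylactic_mix_rate=_rate(first.get("mix_rate_prophylactic")),
        )
    if not products:
        raise ValidationError(f"catalog {path} contains no products")
    return products


def addvet_frame(table: Iterable[AddVetValue]) -> pd.DataFrame:
    """Tabular view of an :func:`addvet_table` result."""
    return pd.DataFrame(
        [
            {
                "aai_name": v.aai_name,
                "mean_add_mg_per_kg_day": v.mean_add_mg_per_kg_day,
                "cv_percent": v.cv_percent,
                "n_products": v.n_products,
                "dddvet_eu_mg_per_kg_day": v.ddd_vet_eu,
            }
            for v in table
        ]
    )
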