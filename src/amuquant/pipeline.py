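"""End-to-end orchestration: validate inputs, run every stage, write tables.

The pipeline is deterministic given (inputs, config): validation runs as a
fail-fast gate that collects *all* violations before any output is written,
then each analysis stage writes its tables plus a machine-readable run
manifest (config hash, package version) for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .catalog import (
    IntakeModel,
    addvet_frame,
    addvet_table,
    classify_products,
    is_quantifiable,
    read_catalog,
    read_classification,
)
from .comparison import aai_concordance, metric_correlations, mortality_stratification
from .errors import FittingError, ValidationError
from .ledger import read_growth_curve, read_record_books
from .metrics import (
    compute_flock_metrics,
    cohort_summary,
    event_aai_mass,
    metrics_frame,
)
from .timing import (
    aai_timing,
    build_use_grid,
    fit_seasonal_model,
    lexis_grid,
    use_probability_by_week,
)

logger = logging.getLogger("amuquant")

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    records: Path
    events: Path
    catalog: Path
    growth: Path
    classification: Path | None = None
    outdir: Path = Path("amu_output")
    water_l_per_kg_day: float = 0.225
    feed_g_per_kg_day: float = 63.4
    ti_denominator: str = "biomass"  # or "per-bird"
    chi_square_correction: bool = False
    growth_curve_empirical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("records", "events", "catalog", "growth", "classification", "outdir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema and cross-file checks; returns ALL violations, not the first.

    Checks that every file exists and parses, that every event references a
    catalog product and an existing flock-week, and that the growth curve
    covers every observed cycle length.  An empty list means the bundle is
    runnable.
    """
    violations: list[str] = []
    for name in ("records", "events", "catalog", "growth"):
        path = getattr(config, name)
        if not Path(path).is_file():
            violations.append(f"{name}: file not found: {path}")
    if config.classification is not None and not config.classification.is_file():
        violations.append(f"classification: file not found: {config.classification}")
    if violations:
        return violations

    classification = {}
    if config.classification is not None:
        try:
            classification, _ = read_classification(config.classification)
        except (ValidationError, ValueError) as exc:
            violations.append(f"classification: {exc}")
    try:
        products = read_catalog(config.catalog, classification)
    except (ValidationError, ValueError) as exc:
        violations.append(f"catalog: {exc}")
        products = {}

    try:
        curve = read_growth_curve(config.growth, config.growth_curve_empirical)
    except (ValidationError, ValueError) as exc:
        violations.append(f"growth: {exc}")
        curve = None

    # row-level record checks are reported individually rather than letting
    # ledger construction stop at the first bad flock
    try:
        records = pd.read_csv(config.records)
        for row in records.itertuples(index=False):
            if row.deaths > row.birds_present:
                violations.append(
                    f"records: flock {row.flock_id} week {row.production_week}: "
                    f"deaths ({row.deaths}) exceed birds present ({row.birds_present})"
                )
        dup = records.duplicated(["flock_id", "production_week"])
        for row in records[dup].itertuples(index=False):
            violations.append(
                f"records: flock {row.flock_id} appears twice at week "
                f"{row.production_week}"
            )
        events = pd.read_csv(config.events)
        known_weeks = set(
            zip(records["flock_id"].astype(str), records["production_week"].astype(int))
        )
        for row in events.itertuples(index=False):
            if products and str(row.product_id) not in products:
                violations.append(
                    f"events: flock {row.flock_id} week {row.production_week}: "
                    f"unknown product {row.product_id!r}"
                )
            if (str(row.flock_id), int(row.production_week)) not in known_weeks:
                violations.append(
                    f"events: flock {row.flock_id} week {row.production_week}: "
                    "no matching record-book row"
                )
            if not row.amount > 0:
                violations.append(
                    f"events: flock {row.flock_id} week {row.production_week}: "
                    f"non-positive amount {row.amount}"
                )
        if curve is not None and not violations:
            try:
                ledgers = read_record_books(config.records, config.events)
            except ValidationError as exc:
                violations.append(f"records: {exc}")
            else:
                longest = max(fl.n_weeks for fl in ledgers.values())
                if longest > curve.max_week:
                    violations.append(
                        f"growth: curve ends at week {curve.max_week} but the "
                        f"longest cycle runs {longest} weeks"
                    )
    except (ValidationError, ValueError) as exc:
        violations.append(f"records/events: {exc}")
    return violations


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write its tables under ``config.outdir``.

    Nothing is written when validation fails (the gate is atomic).  Returns
    a name → path mapping of the written artifacts.
    """
    violations = validate_inputs(config)
    if violations:
        raise ValidationError(
            "input validation failed:\n" + "\n".join(f"- {v}" for v in violations)
        )

    classification = {}
    ddd_reference: dict[str, float] = {}
    if config.classification is not None:
        classification, ddd_reference = read_classification(config.classification)
    products = read_catalog(config.catalog, classification)
    curve = read_growth_curve(config.growth, config.growth_curve_empirical)
    ledgers = read_record_books(config.records, config.events)
    intake = IntakeModel(config.water_l_per_kg_day, config.feed_g_per_kg_day)
    logger.info(
        "loaded %d products, %d flocks, growth curve to week %d",
        len(products),
        len(ledgers),
        curve.max_week,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)

    # --- daily doses and catalog description
    add_values = addvet_table(list(products.values()), intake, ddd_reference)
    save("addvet_table", addvet_frame(add_values))
    save("product_summary", classify_products(list(products.values())))

    # --- flock metrics
    flock_metrics = [
        compute_flock_metrics(
            fl, products, curve, intake, ti_denominator=config.ti_denominator
        )
        for fl in ledgers.values()
    ]
    save("flock_metrics", metrics_frame(flock_metrics))
    aai_classes = {
        ing.aai.name: ing.aai.antimicrobial_class
        for p in products.values()
        for ing in p.ingredients
    }
    summary = cohort_summary(flock_metrics, aai_classes)
    save("cohort_summary", summary.overall)
    save("per_aai_summary", summary.per_aai)
    save("per_class_summary", summary.per_class)
    n_excluded = sum(m.excluded_events for m in flock_metrics)
    logger.info(
        "metrics: %d flocks (%d with birds sold), %d excluded events",
        summary.n_flocks,
        summary.n_flocks_sold,
        n_excluded,
    )

    # --- timing
    grid = build_use_grid(ledgers, products)
    save("use_grid", grid)
    save(
        "weekly_use_probability",
        use_probability_by_week(grid).rename("probability").reset_index(),
    )
    lexis = lexis_grid(grid)
    paths["lexis_grid"] = outdir / "lexis_grid.tsv"
    lexis.to_csv(paths["lexis_grid"], sep="\t")
    try:
        fit = fit_seasonal_model(grid)
        seasonal = fit.frame().reset_index(names="term")
        seasonal.attrs["harmonic_p"] = fit.harmonic_p
        save("seasonal_fit", seasonal)
        (outdir / "seasonal_fit.json").write_text(
            json.dumps(
                {
                    "harmonic_joint_p": fit.harmonic_p,
                    "n_obs": fit.n_obs,
                    "n_clusters": fit.n_clusters,
                },
                indent=1,
            )
        )
    except FittingError as exc:
        logger.warning("seasonal model not fitted: %s", exc)
    save("aai_timing", aai_timing(ledgers, products))

    # --- metric comparison
    corr = metric_correlations(flock_metrics)
    save(
        "metric_correlations",
        pd.DataFrame(
            [
                {
                    "metric_x": c.metric_x,
                    "metric_y": c.metric_y,
                    "pearson_r": c.pearson_r,
                    "p_value": c.p_value,
                    "n_flocks": c.n_flocks,
                }
                for c in corr
            ]
        ),
    )
    strat_rows = []
    for metric in ("mg_per_kg_at_treatment", "mg_per_kg_sold", "treatment_incidence"):
        s = mortality_stratification(
            flock_metrics, metric, continuity_correction=config.chi_square_correction
        )
        strat_rows.append(
            {
                "metric": metric,
                "prop_high_mortality_high_amu": s.prop_high_mortality_high_amu,
                "prop_high_mortality_low_amu": s.prop_high_mortality_low_amu,
                "chi2": s.chi2,
                "p_value": s.p_value,
                "mortality_cut": s.mortality_cut,
                "amu_reference": s.amu_reference,
                "n_flocks": s.n_flocks,
            }
        )
    save("mortality_stratification", pd.DataFrame(strat_rows))

    total_mg_by_aai: dict[str, float] = {}
    for fl in ledgers.values():
        for entry in fl.weeks:
            for event in entry.events:
                product = products[event.product_id]
                if not is_quantifiable(product):
                    continue
                for name, mg in event_aai_mass(event, product).items():
                    total_mg_by_aai[name] = total_mg_by_aai.get(name, 0.0) + mg
    concordance, log_corr = aai_concordance(
        summary.per_aai, addvet_frame(add_values), total_mg_by_aai
    )
    save("aai_concordance", concordance)

    manifest = {
        "package_version": __version__,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_digest": config.digest(),
        "n_flocks": summary.n_flocks,
        "n_products": len(products),
        "excluded_events": n_excluded,
        "log_scale_correlations": log_corr,
    }
    paths["manifest"] = outdir / "run_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
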