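"""How well do the three AMU metrics agree?

Pairwise Pearson correlations across flocks, stratification of mortality
by above/below-average use under each metric, and per-AAI concordance
between dose-based and weight-based summaries.
"""

import argparse
from pathlib import Path

import pandas as pd

from amuquant.catalog import (
    addvet_frame,
    addvet_table,
    is_quantifiable,
    read_catalog,
    read_classification,
)
from amuquant.comparison import aai_concordance, metric_correlations, mortality_stratification
from amuquant.ledger import read_growth_curve, read_record_books
from amuquant.metrics import cohort_summary, compute_flock_metrics, event_aai_mass


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/synthetic_bundle"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    classification, ddd = read_classification(args.bundle / "classification.csv")
    products = read_catalog(args.bundle / "catalog.csv", classification)
    curve = read_growth_curve(args.bundle / "growth_curve.csv")
    ledgers = read_record_books(args.bundle / "records.csv", args.bundle / "events.csv")
    metrics = [compute_flock_metrics(fl, products, curve) for fl in ledgers.values()]

    args.outdir.mkdir(parents=True, exist_ok=True)
    correlations = metric_correlations(metrics)
    pd.DataFrame(
        [
            {
                "metric_x": c.metric_x,
                "metric_y": c.metric_y,
                "pearson_r": c.pearson_r,
                "p_value": c.p_value,
                "n_flocks": c.n_flocks,
            }
            for c in correlations
        ]
    ).to_csv(args.outdir / "metric_correlations.tsv", sep="\t", index=False)
    for c in correlations:
        print(f"{c.metric_x} vs {c.metric_y}: r={c.pearson_r:.3f} "
              f"(p={c.p_value:.2g}, n={c.n_flocks})")

    rows = []
    for metric in ("mg_per_kg_at_treatment", "mg_per_kg_sold", "treatment_incidence"):
        s = mortality_stratification(metrics, metric)
        rows.append(
            {
                "metric": metric,
                "prop_high_mortality_high_amu": s.prop_high_mortality_high_amu,
                "prop_high_mortality_low_amu": s.prop_high_mortality_low_amu,
                "chi2": s.chi2,
                "p_value": s.p_value,
            }
        )
        flag = "significant" if (s.p_value or 1.0) < 0.05 else "not significant"
        print(f"high mortality by {metric}: {s.prop_high_mortality_high_amu:.2f} vs "
              f"{s.prop_high_mortality_low_amu:.2f} (chi2={s.chi2:.2f}, {flag})")
    pd.DataFrame(rows).to_csv(
        args.outdir / "mortality_stratification.tsv", sep="\t", index=False
    )

    aai_classes = {a.name: a.antimicrobial_class for a in classification.values()}
    summary = cohort_summary(metrics, aai_classes)
    totals: dict[str, float] = {}
    for fl in ledgers.values():
        for entry in fl.weeks:
            for event in entry.events:
                product = products[event.product_id]
                if not is_quantifiable(product):
                    continue
                for name, mg in event_aai_mass(event, product).items():
                    totals[name] = totals.get(name, 0.0) + mg
    add = addvet_frame(addvet_table(list(products.values()), ddd_reference=ddd))
    joined, log_corr = aai_concordance(summary.per_aai, add, totals)
    joined.to_csv(args.outdir / "aai_concordance.tsv", sep="\t", index=False)
    for key, value in log_corr.items():
        if value is not None:
            print(f"{key}: r={value:.3f}")


if __name__ == "__main__":
    main()
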