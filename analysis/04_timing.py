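"""When are flocks medicated? Weekly probabilities, Lexis grid, seasonality.

Computes the probability of any antimicrobial use by production week, the
age x calendar Lexis surface, the cluster-robust seasonal logistic model,
and the per-AAI timing distributions.
"""

import argparse
import json
from pathlib import Path

from amuquant.catalog import read_catalog, read_classification
from amuquant.errors import FittingError
from amuquant.ledger import read_record_books
from amuquant.timing import (
    aai_timing,
    build_use_grid,
    fit_seasonal_model,
    lexis_grid,
    use_probability_by_week,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/synthetic_bundle"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    classification, _ = read_classification(args.bundle / "classification.csv")
    products = read_catalog(args.bundle / "catalog.csv", classification)
    ledgers = read_record_books(args.bundle / "records.csv", args.bundle / "events.csv")

    grid = build_use_grid(ledgers, products)
    args.outdir.mkdir(parents=True, exist_ok=True)
    weekly = use_probability_by_week(grid)
    weekly.rename("probability").reset_index().to_csv(
        args.outdir / "weekly_use_probability.tsv", sep="\t", index=False
    )
    lexis_grid(grid).to_csv(args.outdir / "lexis_grid.tsv", sep="\t")
    timing = aai_timing(ledgers, products)
    timing.to_csv(args.outdir / "aai_timing.tsv", sep="\t", index=False)

    print(f"use probability: week 1 {weekly.loc[1]:.2f}, week 2 {weekly.loc[2]:.2f}, "
          f"week {weekly.index.max()} {weekly.iloc[-1]:.2f}")
    try:
        fit = fit_seasonal_model(grid)
        (args.outdir / "seasonal_fit.json").write_text(
            json.dumps(
                {
                    "coefficients": fit.params.to_dict(),
                    "cluster_se": fit.bse.to_dict(),
                    "p_values": fit.pvalues.to_dict(),
                    "harmonic_joint_p": fit.harmonic_p,
                    "n_obs": fit.n_obs,
                    "n_clusters": fit.n_clusters,
                },
                indent=1,
            )
        )
        print(f"age effect {fit.params['production_week']:.3f} log-odds/week "
              f"(p={fit.pvalues['production_week']:.2g}); "
              f"seasonal harmonic joint p={fit.harmonic_p:.3f} "
              f"({'' if fit.harmonic_p < 0.05 else 'not '}significant at 0.05)")
    except FittingError as exc:
        print(f"seasonal model not fitted: {exc}")
    early = timing.nsmallest(3, "median_week")["aai_name"].tolist()
    print(f"earliest-used AAIs (median week): {', '.join(early)}")


if __name__ == "__main__":
    main()
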