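"""Agreement between the three flock-level AMU metrics.

Weight-based metrics (mg/kg at treatment, mg/kg sold) and the dose-based
treatment incidence need not rank flocks the same way: they are pulled
apart by ingredient strength (a gram of a weak drug is many doses of a
strong one), by mortality (which shrinks the mg/kg-sold denominator), and
by treatment timing (early treatments hit a small biomass).  This module
quantifies that agreement: pairwise Pearson correlations across flocks, a
2×2 mortality stratification with a chi-square test, and per-AAI
concordance between dose- and weight-based summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .metrics import FlockMetrics

__all__ = [
    "MetricCorrelation",
    "metric_correlations",
    "StratificationResult",
    "mortality_stratification",
    "aai_concordance",
    "pearson_with_p",
]

_METRICS = ("mg_per_kg_at_treatment", "mg_per_kg_sold", "treatment_incidence")
_PAIRS = (
    ("mg_per_kg_at_treatment", "mg_per_kg_sold"),
    ("mg_per_kg_at_treatment", "treatment_incidence"),
    ("mg_per_kg_sold", "treatment_incidence"),
)


@dataclass(frozen=True)
class MetricCorrelation:
    metric_x: str
    metric_y: str
    pearson_r: float | None  # None when undefined (constant input)
    p_value: float | None
    n_flocks: int


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    """Pearson r and its two-sided t-test p; (None, None) if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def metric_correlations(
    flock_metrics: Sequence[FlockMetrics],
) -> list[MetricCorrelation]:
    """Pairwise Pearson correlations between the three metrics.

    Flocks lacking ``mg/kg sold`` (100% mortality) are dropped pairwise, so
    each pair uses the largest available n.  Zero-variance inputs yield an
    undefined correlation, flagged as ``None`` rather than an error.
    """
    if len(flock_metrics) < 3:
        raise ValidationError("need at least 3 flocks for correlations")
    out = []
    for mx, my in _PAIRS:
        pairs = [
            (getattr(m, mx), getattr(m, my))
            for m in flock_metrics
            if getattr(m, mx) is not None and getattr(m, my) is not None
        ]
        arr = np.asarray(pairs, dtype=float)
        r, p = (None, None) if arr.shape[0] < 3 else pearson_with_p(arr[:, 0], arr[:, 1])
        out.append(
            MetricCorrelation(
                metric_x=mx,
                metric_y=my,
                pearson_r=r,
                p_value=p,
                n_flocks=arr.shape[0],
            )
        )
    return out


@dataclass(frozen=True)
class StratificationResult:
    """High-mortality proportions among high vs low AMU flocks."""

    metric: str
    table: np.ndarray  # rows: AMU high/low; cols: mortality high/low
    prop_high_mortality_high_amu: float
    prop_high_mortality_low_amu: float
    chi2: float | None  # None when a margin is empty
    p_value: float | None
    mortality_cut: float
    amu_reference: float
    n_flocks: int


def mortality_stratification(
    flock_metrics: Sequence[FlockMetrics],
    metric: str = "mg_per_kg_sold",
    mortality_cut: float | None = None,
    continuity_correction: bool = False,
) -> StratificationResult:
    """Cross-classify flocks by AMU level and mortality, with a chi-square.

    "High AMU" is strictly above the cohort mean of the chosen metric;
    "high mortality" is at or above ``mortality_cut`` (default: the cohort
    median cumulative mortality).  The Pearson chi-square (1 df) is computed
    without continuity correction by default.  If any table margin is zero
    the table is still returned with the test marked undefined.
    """
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    rows = [
        (getattr(m, metric), m.cumulative_mortality)
        for m in flock_metrics
        if getattr(m, metric) is not None
    ]
    if not rows:
        raise ValidationError(f"no flocks with metric {metric!r} defined")
    values = np.asarray([r[0] for r in rows], dtype=float)
    mort = np.asarray([r[1] for r in rows], dtype=float)
    if mortality_cut is None:
        mortality_cut = float(np.median(mort))
    amu_reference = float(values.mean())

    high_amu = values > amu_reference
    high_mort = mort >= mortality_cut
    table = np.array(
        [
            [np.sum(high_amu & high_mort), np.sum(high_amu & ~high_mort)],
            [np.sum(~high_amu & high_mort), np.sum(~high_amu & ~high_mort)],
        ],
        dtype=float,
    )
    n_high = table[0].sum()
    n_low = table[1].sum()
    prop_high = table[0, 0] / n_high if n_high else float("nan")
    prop_low = table[1, 0] / n_low if n_low else float("nan")

    chi2 = p = None
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2_val, p_val, _, _ = stats.chi2_contingency(
            table, correction=continuity_correction
        )
        chi2, p = float(chi2_val), float(p_val)
    return StratificationResult(
        metric=metric,
        table=table,
        prop_high_mortality_high_amu=float(prop_high),
        prop_high_mortality_low_amu=float(prop_low),
        chi2=chi2,
        p_value=p,
        mortality_cut=mortality_cut,
        amu_reference=amu_reference,
        n_flocks=len(rows),
    )


def aai_concordance(
    per_aai_summary: pd.DataFrame,
    addvet: pd.DataFrame,
    total_mg_by_aai: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Join per-AAI cohort metrics with daily-dose values; log-scale r.

    ``per_aai_summary`` is the ``per_aai`` table of a cohort summary;
    ``addvet`` the daily-dose table (``aai_name``,
    ``mean_add_mg_per_kg_day``).  ``total_mg_by_aai`` — cohort-total AAI
    masses aggregated from event records — adds a ``total_g`` column (the
    "total weight ignoring population treated" view).  Returns the joined
    table (AAIs missing on either side flagged ``matched=False``) and
    base-10 log-scale Pearson correlations of treatment incidence against
    each weight-based quantity; zero-use AAIs are excluded from the
    log-scale correlations and remain visible in the table.
    """
    joined = per_aai_summary.merge(
        addvet[["aai_name", "mean_add_mg_per_kg_day", "n_products"]],
        on="aai_name",
        how="outer",
        indicator=True,
    )
    joined["matched"] = joined["_merge"] == "both"
    joined = joined.drop(columns="_merge")
    if total_mg_by_aai is not None:
        joined["total_g"] = joined["aai_name"].map(
            lambda n: total_mg_by_aai.get(n, 0.0) / 1000.0
        )

    candidates = ["mg_per_kg_at_treatment_mean", "mean_add_mg_per_kg_day"]
    if total_mg_by_aai is not None:
        candidates.append("total_g")
    correlations: dict[str, float | None] = {}
    for col in candidates:
        if col not in joined.columns:
            continue
        sub = joined[
            (joined["matched"])
            & (joined["treatment_incidence_mean"] > 0)
            & (joined[col] > 0)
        ]
        if len(sub) < 3:
            correlations[f"log10_ti_vs_{col}"] = None
            continue
        r, _ = pearson_with_p(
            np.log10(sub["treatment_incidence_mean"].to_numpy()),
            np.log10(sub[col].to_numpy()),
        )
        correlations[f"log10_ti_vs_{col}"] = r
    return joined, correlations
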