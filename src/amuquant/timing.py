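"""When flocks are medicated: weekly probabilities, Lexis grid, seasonality.

The observation unit is the flock-week.  A flock-week is "used" when at
least one antimicrobial-containing product was administered that week —
including injectables and human medicines, since descriptive timing is
broader than the quantifiable-dose scope.  Flocks enter at different
calendar dates, so the panel has a Lexis structure: each flock traces a
diagonal lifeline through the (production week × calendar week) plane.

Seasonality is tested with a logistic model of weekly use on flock age plus
one annual harmonic pair (sin, cos of calendar week), with standard errors
clustered on flock identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog import Product
from .errors import FittingError, ValidationError
from .ledger import FlockLedger, calendar_index

__all__ = [
    "build_use_grid",
    "use_probability_by_week",
    "lexis_grid",
    "harmonic_features",
    "SeasonalFit",
    "fit_seasonal_model",
    "aai_timing",
]


def build_use_grid(
    ledgers: Mapping[str, FlockLedger],
    products: Mapping[str, Product],
    origin: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Flock-week panel of binary antimicrobial-use indicators.

    Columns: ``flock_id, production_week, calendar_index, used``;
    ``calendar_index`` counts study weeks from ``origin`` (default: the
    earliest ISO week observed).  Duplicate events within a week collapse to
    a single 1.
    """
    if not ledgers:
        raise ValidationError("no ledgers supplied")
    if origin is None:
        first = min(
            ((w.iso_year, w.iso_week) for fl in ledgers.values() for w in fl.weeks)
        )
        origin = first
    rows = []
    for flock in ledgers.values():
        for entry in flock.weeks:
            used = any(
                products[e.product_id].is_antimicrobial
                for e in entry.events
                if e.product_id in products
            )
            rows.append(
                {
                    "flock_id": flock.flock_id,
                    "production_week": entry.production_week,
                    "calendar_index": calendar_index(
                        entry.iso_year, entry.iso_week, origin
                    ),
                    "used": int(used),
                }
            )
    grid = pd.DataFrame(rows)
    if grid.duplicated(["flock_id", "production_week"]).any():
        raise ValidationError("duplicate (flock, production week) rows in grid")
    return grid


def use_probability_by_week(grid: pd.DataFrame) -> pd.Series:
    """P(any AMU) by production week: medicated flocks / flocks observed."""
    if grid.empty:
        raise ValidationError("empty use grid")
    return grid.groupby("production_week")["used"].mean()


def lexis_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Use probability indexed by (production week × calendar week).

    Cells with no observed flock-week are NaN (unobserved, never zero).
    Rows are production weeks, columns calendar indices.
    """
    if grid.empty:
        raise ValidationError("empty use grid")
    return grid.pivot_table(
        index="production_week",
        columns="calendar_index",
        values="used",
        aggfunc="mean",
    )


def harmonic_features(
    calendar_week_index: np.ndarray | float, period: float = 52.0
) -> tuple[np.ndarray, np.ndarray]:
    """Annual harmonic pair sin(2πt/period), cos(2πt/period)."""
    if period <= 0:
        raise ValidationError("harmonic period must be > 0")
    t = np.asarray(calendar_week_index, dtype=float)
    angle = 2.0 * np.pi * t / period
    return np.sin(angle), np.cos(angle)


@dataclass(frozen=True)
class SeasonalFit:
    """Cluster-robust logistic fit of weekly use on age and season."""

    params: pd.Series  # intercept, production_week, sin, cos (log-odds)
    bse: pd.Series
    pvalues: pd.Series
    harmonic_p: float  # joint Wald p-value for the sin+cos pair
    n_obs: int
    n_clusters: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p_value": self.pvalues}
        )


def fit_seasonal_model(grid: pd.DataFrame, period: float = 52.0) -> SeasonalFit:
    """Fit ``used ~ production_week + sin + cos`` with flock-clustered SEs.

    Uses a binomial GLM with a sandwich covariance clustered on flock
    identity (the assumption-light reading of "flock as clustering
    variable").  The harmonic pair is tested jointly with a 2-df Wald test.

    Raises
    ------
    FittingError
        Fewer than 2 clusters, a single-class outcome, or IRLS failure
        (e.g. perfect separation).
    """
    if grid.empty:
        raise ValidationError("empty use grid")
    n_clusters = grid["flock_id"].nunique()
    if n_clusters < 2:
        raise FittingError("need at least 2 flocks (clusters) to fit")
    if grid["used"].nunique() < 2:
        raise FittingError("outcome has a single class; model not identifiable")

    sin_t, cos_t = harmonic_features(grid["calendar_index"].to_numpy(), period)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "production_week": grid["production_week"].to_numpy(dtype=float),
            "sin_annual": sin_t,
            "cos_annual": cos_t,
        },
        index=grid.index,
    )
    model = sm.GLM(grid["used"], X, family=sm.families.Binomial())
    try:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": grid["flock_id"]}
        )
    except Exception as exc:  # separation / convergence failure
        raise FittingError(f"seasonal logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse <= 0):
        raise FittingError("non-finite standard errors (possible separation)")

    wald = res.wald_test(
        np.array([[0.0, 0.0, 1.0, 0.0], [0.0, 0.0, 0.0, 1.0]]), scalar=True
    )
    return SeasonalFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        harmonic_p=float(wald.pvalue),
        n_obs=int(res.nobs),
        n_clusters=int(n_clusters),
    )


def aai_timing(
    ledgers: Mapping[str, FlockLedger],
    products: Mapping[str, Product],
) -> pd.DataFrame:
    """Median and IQR of the production week of use, per AAI.

    One observation per flock-week in which the AAI was administered
    (unweighted by mass); AAIs never used are simply absent.
    """
    weeks_by_aai: dict[str, list[int]] = {}
    for flock in ledgers.values():
        for entry in flock.weeks:
            names = set()
            for event in entry.events:
                product = products.get(event.product_id)
                if product is None:
                    continue
                names.update(ing.aai.name for ing in product.ingredients)
            for name in names:
                weeks_by_aai.setdefault(name, []).append(entry.production_week)
    rows = []
    for name in sorted(weeks_by_aai):
        arr = np.asarray(weeks_by_aai[name], dtype=float)
        q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
        rows.append(
            {
                "aai_name": name,
                "n_flock_weeks": arr.size,
                "median_week": float(q50),
                "q25_week": float(q25),
                "q75_week": float(q75),
            }
        )
    return pd.DataFrame(rows)
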