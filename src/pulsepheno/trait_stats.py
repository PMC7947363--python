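"""Pearson correlation of image features against agronomic traits.

Two analysis modes: plot-by-plot (every plot is an observation) and
cultivar-by-cultivar (replicates averaged per entry within each field site).
Significance stars follow the conventional raw-alpha thresholds 0.05, 0.01
and 0.001; no multiple-testing correction is applied, so star counts across a
large feature x trait matrix must be read accordingly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["pearson", "stars", "aggregate_cultivar", "correlate"]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Pairs with a missing value in either vector are dropped (pairwise
    deletion). Returns ``(r, p, n)``; ``r`` and ``p`` are NaN when fewer than
    3 complete pairs remain or either vector is constant (r undefined).
    p = 2 P(T_{n-2} >= |r| sqrt((n-2)/(1-r^2))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return np.nan, np.nan, n
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return np.nan, np.nan, n
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p, n


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate_cultivar(
    table: pd.DataFrame, value_cols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Average replicates per (entry, location[, date, stage]).

    Arithmetic mean of each value column over replicates; missing values are
    excluded from each mean. A single replicate passes through unchanged.
    """
    if "entry" not in table.columns or "rep" not in table.columns:
        raise ValueError("table needs 'entry' and 'rep' columns to average replicates")
    keys = [c for c in ("entry", "location", "date", "stage") if c in table.columns]
    if value_cols is None:
        value_cols = [
            c
            for c in table.columns
            if c not in keys + ["rep", "plot"] and pd.api.types.is_numeric_dtype(table[c])
        ]
    out = table.groupby(keys, as_index=False, sort=True)[list(value_cols)].mean()
    return out


def correlate(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    trait_cols: Sequence[str],
    mode: str = "plot",
    stage: str = "",
    exclude_plots: Sequence | None = None,
) -> pd.DataFrame:
    """Feature x trait Pearson correlation matrix in long format.

    ``mode`` is ``"plot"`` (rows as-is) or ``"cultivar"`` (replicates averaged
    first). ``exclude_plots`` drops the named plot ids before analysis — the
    explicit stand-in for removing noisy observations (e.g. cloud-covered
    plots); nothing is removed automatically. Output columns:
    feature, trait, stage, mode, r, p, stars, n (plus ``note`` for undefined
    correlations such as constant inputs).
    """
    if mode not in ("plot", "cultivar"):
        raise ValueError("mode must be 'plot' or 'cultivar'")
    df = table
    if exclude_plots is not None and "plot" in df.columns:
        df = df[~df["plot"].isin(list(exclude_plots))]
    if mode == "cultivar":
        df = aggregate_cultivar(df, list(dict.fromkeys(list(feature_cols) + list(trait_cols))))
    rows = []
    for feat in feature_cols:
        for trait in trait_cols:
            r, p, n = pearson(df[feat].to_numpy(), df[trait].to_numpy())
            note = ""
            if not np.isfinite(r):
                note = "undefined (constant input or <3 pairs)"
            rows.append(
                {
                    "feature": feat,
                    "trait": trait,
                    "stage": stage,
                    "mode": mode,
                    "r": r,
                    "p": p,
                    "stars": stars(p),
                    "n": n,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
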