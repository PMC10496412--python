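"""Mutation-vs-selection diagnostics.

Three classical plots distinguish mutational pressure from selection on
codon usage:

* **Nc–GC3s plot** — observed Nc against Wright's expected curve under a
  neutral mutation model, ``Nc_exp(s) = 2 + s + 29/(s² + (1-s)²)``;
  genes below the curve are more biased than composition alone explains.
* **Neutrality plot** — OLS regression of GC3 on GC12 (x = GC12,
  y = GC3); a slope near 1 means a shared mutational process drives all
  codon positions, a slope near 0 means the third position is decoupled
  (selection-dominated).
* **PR2 plot** — G3/(G3+C3) vs A3/(A3+T3); (0.5, 0.5) is the
  no-strand-bias point, quadrant occupancy shows which third-position
  bases are favoured.

Plus the Pearson correlation matrix over the metric columns.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NeutralityFit",
    "expected_nc",
    "nc_deviation",
    "neutrality_regression",
    "pr2_analysis",
    "correlation_matrix",
]


def expected_nc(gc3s):
    """Wright's expected Nc under neutrality for silent-site GC ``gc3s``.

    Accepts a scalar or array; Nc_exp(0.5) = 60.5, Nc_exp(0) = 31,
    Nc_exp(1) = 32.
    """
    s = np.asarray(gc3s, dtype=float)
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class NeutralityFit:
    """OLS fit of the neutrality plot (default axes x=GC12, y=GC3)."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int
    stderr: float
    x_name: str = "GC12"
    y_name: str = "GC3"

    @property
    def slope_percent(self) -> float:
        """Slope as the percentage of variation attributed to mutation."""
        return 100.0 * self.slope

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.stderr
        return self.slope - half, self.slope + half


def nc_deviation(metrics: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-gene deviation from Wright's curve, Nc_exp(GC3s) - Nc_obs.

    Positive deviations lie *below* the curve (more biased than the
    neutral expectation).  Returns the per-gene table and the fraction
    of genes with positive deviation.
    """
    df = metrics.dropna(subset=["Nc", "GC3s"])[["gene_id", "Nc", "GC3s"]].copy()
    df["nc_expected"] = expected_nc(df["GC3s"].to_numpy())
    df["deviation"] = df["nc_expected"] - df["Nc"]
    frac_below = float((df["deviation"] > 0).mean()) if len(df) else math.nan
    return df, frac_below


def neutrality_regression(
    metrics: pd.DataFrame, *, transpose: bool = False
) -> NeutralityFit:
    """Neutrality-plot regression (x = GC12, y = GC3 by default).

    ``transpose=True`` swaps the axes to the orientation more common in
    the wider literature (x = GC3, y = GC12).
    """
    x_name, y_name = ("GC3", "GC12") if transpose else ("GC12", "GC3")
    df = metrics.dropna(subset=[x_name, y_name])
    if len(df) < 3:
        raise ValueError(f"need >= 3 genes for regression, got {len(df)}")
    x = df[x_name].to_numpy()
    y = df[y_name].to_numpy()
    if np.ptp(x) == 0:
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan,
                             len(df), math.nan, x_name, y_name)
    fit = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), p=float(fit.pvalue), n=len(df),
        stderr=float(fit.stderr), x_name=x_name, y_name=y_name,
    )


def pr2_analysis(metrics: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parity-rule-2 coordinates and quadrant occupancy.

    x = G3/(G3+C3), y = A3/(A3+T3).  Quadrants: Q1 x>0.5,y>0.5;
    Q2 x<0.5,y>0.5; Q3 x<0.5,y<0.5; Q4 x>0.5,y<0.5.  Points with x or y
    exactly 0.5 are counted as ``boundary`` (the centre is assigned to
    no quadrant); genes with a zero denominator are ``excluded``.
    """
    rows = []
    counts = {q: 0 for q in ("Q1", "Q2", "Q3", "Q4", "boundary", "excluded")}
    for _, g in metrics.iterrows():
        a3, t3, g3, c3 = (g[k] for k in ("A3", "T3", "G3", "C3"))
        if any(math.isnan(v) for v in (a3, t3, g3, c3)) or (g3 + c3) == 0 or (a3 + t3) == 0:
            counts["excluded"] += 1
            rows.append({"gene_id": g["gene_id"], "x": math.nan, "y": math.nan,
                         "quadrant": "excluded"})
            continue
        x = g3 / (g3 + c3)
        y = a3 / (a3 + t3)
        if x == 0.5 or y == 0.5:
            quad = "boundary"
        elif x > 0.5:
            quad = "Q1" if y > 0.5 else "Q4"
        else:
            quad = "Q2" if y > 0.5 else "Q3"
        counts[quad] += 1
        rows.append({"gene_id": g["gene_id"], "x": x, "y": y, "quadrant": quad})
    return pd.DataFrame(rows, columns=["gene_id", "x", "y", "quadrant"]), counts


#: default 12-parameter list for the correlation analysis
DEFAULT_CORRELATION_PARAMS = (
    "GC", "GC1", "GC2", "GC3", "GC12", "GC3s",
    "A3", "T3", "G3", "C3", "Nc", "Fop",
)


def correlation_matrix(
    metrics: pd.DataFrame,
    params: Sequence[str] = DEFAULT_CORRELATION_PARAMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-tailed p over metric columns.

    Returns (r, p) DataFrames, symmetric with unit diagonal.  Pairs with
    zero variance in either column give nan.
    """
    params = [p for p in params if p in metrics.columns]
    k = len(params)
    r = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], pv[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            sub = metrics[[params[i], params[j]]].dropna()
            x, y = sub[params[i]].to_numpy(), sub[params[j]].to_numpy()
            if len(sub) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                pv[i, j] = pv[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=params, columns=params),
        pd.DataFrame(pv, index=params, columns=params),
    )
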