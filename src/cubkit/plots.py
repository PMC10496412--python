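"""Diagnostic scatter plots (Nc–GC3s, neutrality, PR2)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .selection_mutation import expected_nc, neutrality_regression, pr2_analysis

__all__ = ["nc_gc3s_plot", "neutrality_plot", "pr2_plot", "save_all_plots"]


def nc_gc3s_plot(metrics: pd.DataFrame, ax=None):
    """Observed Nc against GC3s with Wright's neutral expectation curve."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(metrics["GC3s"], metrics["Nc"], s=4, alpha=0.4, label="genes")
    s = np.linspace(0.01, 0.99, 200)
    ax.plot(s, expected_nc(s), "k-", lw=1.2, label="neutral expectation")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("Nc")
    ax.set_ylim(15, 63)
    ax.legend(frameon=False)
    return ax


def neutrality_plot(metrics: pd.DataFrame, ax=None, *, transpose: bool = False):
    """GC3 against GC12 with the OLS fit line."""
    if ax is None:
        _, ax = plt.subplots()
    fit = neutrality_regression(metrics, transpose=transpose)
    x = metrics[fit.x_name]
    ax.scatter(x, metrics[fit.y_name], s=4, alpha=0.4)
    xs = np.linspace(float(x.min()), float(x.max()), 10)
    ax.plot(xs, fit.slope * xs + fit.intercept, "k-", lw=1.2)
    ax.set_xlabel(fit.x_name)
    ax.set_ylabel(fit.y_name)
    ax.set_title(f"y = {fit.slope:.3f}x + {fit.intercept:.3f}  (r = {fit.r:.3f})")
    return ax


def pr2_plot(metrics: pd.DataFrame, ax=None):
    """G3/(G3+C3) vs A3/(A3+T3) with crosshairs at the 0.5 centre."""
    if ax is None:
        _, ax = plt.subplots()
    points, _ = pr2_analysis(metrics)
    ax.scatter(points["x"], points["y"], s=4, alpha=0.4)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def save_all_plots(metrics: pd.DataFrame, outdir: str | Path, fmt: str = "png") -> list[Path]:
    """Write the three diagnostic plots to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fn in (
        ("nc_gc3s", nc_gc3s_plot),
        ("neutrality", neutrality_plot),
        ("pr2", pr2_plot),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        fn(metrics, ax)
        path = outdir / f"{name}.{fmt}"
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
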