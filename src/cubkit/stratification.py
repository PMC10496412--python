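"""Bias-category stratification and optimal-codon identification.

Genes are ranked by Nc and the extreme percentiles (5–10% per species in
the red-algal study) become the high-bias (putatively highly expressed)
and low-bias categories; the rest are mid-bias.  Optimal codons are the
codons whose pooled RSCU in the high category exceeds the low category
by more than 0.08.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable, rscu
from .genetic_code import STOP_CODONS, SYNONYMOUS_FAMILIES

__all__ = [
    "BiasPartition",
    "OptimalCodon",
    "OptimalCodonSet",
    "assign_bias_categories",
    "identify_optimal_codons",
    "stop_codon_usage",
    "category_gc_comparison",
]

CATEGORIES = ("high", "mid", "low")


@dataclass
class BiasPartition:
    """Assignment of genes to high/mid/low bias categories by Nc rank."""

    assignments: dict[str, str]  # gene id -> 'high' | 'mid' | 'low'
    p: float
    excluded: list[str] = field(default_factory=list)  # undefined-Nc genes
    degenerate: bool = False  # all Nc equal; id tie-break decided everything

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.assignments.values())
        return {cat: c.get(cat, 0) for cat in CATEGORIES}

    def genes(self, category: str) -> list[str]:
        return [g for g, c in self.assignments.items() if c == category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.assignments), "category": list(self.assignments.values())}
        )


@dataclass
class OptimalCodon:
    codon: str
    amino_acid: str
    rscu_high: float
    rscu_low: float

    @property
    def delta(self) -> float:
        return self.rscu_high - self.rscu_low


@dataclass
class OptimalCodonSet:
    """Per-genome optimal codons with their ΔRSCU evidence."""

    codons: dict[str, OptimalCodon]
    threshold: float = 0.08
    optimal_stop: tuple[str, ...] = ()  # modal stop codon(s) in the high pool
    skipped_families: list[str] = field(default_factory=list)

    @property
    def codon_set(self) -> set[str]:
        return set(self.codons)

    def for_amino_acid(self, aa: str) -> list[str]:
        return [c for c, o in self.codons.items() if o.amino_acid == aa]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "amino_acid": o.amino_acid,
                "codon": c,
                "rscu_high": o.rscu_high,
                "rscu_low": o.rscu_low,
                "delta_rscu": o.delta,
            }
            for c, o in sorted(self.codons.items(), key=lambda kv: (kv[1].amino_acid, kv[0]))
        ]
        return pd.DataFrame(
            rows, columns=["amino_acid", "codon", "rscu_high", "rscu_low", "delta_rscu"]
        )


def assign_bias_categories(metrics: pd.DataFrame, p: float) -> BiasPartition:
    """Partition genes into high/mid/low bias categories by Nc.

    The ``⌊p·N⌋`` genes with the lowest Nc are the high-bias category and
    the ``⌊p·N⌋`` with the highest Nc the low-bias category.  Genes with
    undefined Nc are excluded (and recorded); ties at either boundary are
    broken by ascending gene id, so the partition is deterministic.
    """
    if not 0 < p <= 0.5:
        raise ValueError(f"p must be in (0, 0.5], got {p}")
    df = metrics[["gene_id", "Nc"]].copy()
    excluded = df.loc[df["Nc"].isna(), "gene_id"].tolist()
    df = df.dropna(subset=["Nc"])
    n = len(df)
    k = int(p * n)
    if k == 0:
        raise ValueError(f"category empty: floor(p*N) = 0 with p={p}, N={n}")
    asc = df.sort_values(["Nc", "gene_id"], ascending=[True, True])
    high = set(asc["gene_id"].head(k))
    rest = df[~df["gene_id"].isin(high)]
    desc = rest.sort_values(["Nc", "gene_id"], ascending=[False, True])
    low = set(desc["gene_id"].head(k))
    assignments = {
        g: ("high" if g in high else "low" if g in low else "mid")
        for g in df["gene_id"]
    }
    return BiasPartition(
        assignments=assignments,
        p=p,
        excluded=excluded,
        degenerate=bool(n > 1 and df["Nc"].nunique() == 1),
    )


def identify_optimal_codons(
    high: CodonCountTable,
    low: CodonCountTable,
    threshold: float = 0.08,
    *,
    strict: bool = False,
) -> OptimalCodonSet:
    """Optimal codons from pooled high- vs low-category RSCU.

    A codon is optimal iff RSCU_high - RSCU_low > ``threshold`` (strict
    inequality).  ``strict=True`` additionally requires RSCU_high > 1.
    Families absent from either pool are skipped and recorded.  The
    modal stop codon of the high pool is reported as the optimal
    termination codon (all tied codons on a tie).
    """
    rscu_high = rscu(high)
    rscu_low = rscu(low)
    codons: dict[str, OptimalCodon] = {}
    skipped: list[str] = []
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if math.isnan(rscu_high[fam[0]]) or math.isnan(rscu_low[fam[0]]):
            skipped.append(aa)
            continue
        for c in fam:
            delta = rscu_high[c] - rscu_low[c]
            if delta > threshold and (not strict or rscu_high[c] > 1):
                codons[c] = OptimalCodon(c, aa, rscu_high[c], rscu_low[c])
    stop_mode: tuple[str, ...] = ()
    if high.stops:
        mx = max(high.stops.values())
        stop_mode = tuple(s for s in STOP_CODONS if high.stops.get(s) == mx)
    return OptimalCodonSet(
        codons=codons,
        threshold=threshold,
        optimal_stop=stop_mode,
        skipped_families=skipped,
    )


def stop_codon_usage(
    tables: Iterable[CodonCountTable] | CodonCountTable,
) -> pd.DataFrame:
    """Stop-codon counts and frequencies with the modal ("optimal") stop.

    Accepts a pooled table or an iterable of per-gene tables.  Ties for
    the mode are reported as multiple modal rows.
    """
    if isinstance(tables, CodonCountTable):
        pooled = tables
    else:
        pooled = CodonCountTable.pool(tables)
    total = sum(pooled.stops.values())
    mx = max((pooled.stops.get(s, 0) for s in STOP_CODONS), default=0)
    rows = [
        {
            "stop_codon": s,
            "count": pooled.stops.get(s, 0),
            "frequency": pooled.stops.get(s, 0) / total if total else math.nan,
            "modal": total > 0 and pooled.stops.get(s, 0) == mx,
        }
        for s in STOP_CODONS
    ]
    return pd.DataFrame(rows)


def category_gc_comparison(
    partition: BiasPartition,
    values: pd.DataFrame,
    columns: Iterable[str] = ("GC3s", "flank_gc", "intron_gc"),
) -> pd.DataFrame:
    """Per-category GC summaries with Welch t-tests between categories.

    ``values`` needs a ``gene_id`` column plus the requested value
    columns (missing values allowed — e.g. intronless genes).  For each
    column the high-vs-mid and mid-vs-low comparisons are tested with a
    two-tailed Welch t-test; a category with fewer than two non-missing
    values skips the test (reported as nan with ``tested=False``).
    """
    cat = values["gene_id"].map(partition.assignments)
    rows = []
    for col in columns:
        by_cat = {
            c: values.loc[(cat == c) & values[col].notna(), col].to_numpy()
            for c in CATEGORIES
        }
        for c in CATEGORIES:
            v = by_cat[c]
            rows.append({
                "variable": col, "kind": "summary", "category": c,
                "comparison": "", "n": len(v),
                "mean": float(np.mean(v)) if len(v) else math.nan,
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan,
                "t": math.nan, "p": math.nan, "tested": False,
            })
        for a, b in (("high", "mid"), ("mid", "low")):
            va, vb = by_cat[a], by_cat[b]
            ok = len(va) >= 2 and len(vb) >= 2
            if ok:
                t, pval = stats.ttest_ind(va, vb, equal_var=False)
            else:
                t, pval = math.nan, math.nan
            rows.append({
                "variable": col, "kind": "test", "category": "",
                "comparison": f"{a}_vs_{b}", "n": len(va) + len(vb),
                "mean": math.nan, "sd": math.nan,
                "t": float(t), "p": float(pval), "tested": ok,
            })
    return pd.DataFrame(rows)
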