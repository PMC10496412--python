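"""Domain vs nondomain codon usage within genes.

Each gene's codons are split into protein-domain codons (CDD-style
interval annotations, in codon units) and the remainder, and Fop is
compared between the two segments within each bias category.  Genes are
excluded when they carry no domain annotation, or when the domain spans
every codon (optionally excepting the start and/or stop codon) so that
one of the segments would be trivial.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable, count_codons, fop
from .stratification import BiasPartition, CATEGORIES

__all__ = [
    "DomainAnnotation",
    "partition_codons",
    "segment_fop_table",
    "domain_fop_comparison",
    "cdd_hit_to_codon_interval",
]


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class DomainAnnotation:
    """Domain intervals of one gene, 0-based half-open in codon units."""

    gene_id: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.intervals = _merge(self.intervals)

    def covered(self, length_codons: int) -> set[int]:
        out: set[int] = set()
        for s, e in self.intervals:
            if s < 0 or e > length_codons:
                raise ValueError(
                    f"domain interval [{s}, {e}) out of bounds for gene "
                    f"{self.gene_id} of {length_codons} codons"
                )
            out.update(range(s, e))
        return out


def cdd_hit_to_codon_interval(aa_from: int, aa_to: int) -> tuple[int, int]:
    """1-based inclusive amino-acid CDD coordinates -> codon interval."""
    return aa_from - 1, aa_to


def partition_codons(
    cds: str, annot: DomainAnnotation | None
) -> tuple[CodonCountTable, CodonCountTable] | str:
    """Split a CDS's codons into domain and nondomain count tables.

    Returns the pair of tables, or an exclusion reason string when the
    gene cannot contribute: no annotation, or a domain spanning all
    codons (optionally except the start and/or stop).
    """
    length = len(cds) // 3
    if annot is None or not annot.intervals:
        return "no_domain_annotation"
    covered = annot.covered(length)
    uncovered = set(range(length)) - covered
    if uncovered <= {0, length - 1}:
        return "domain_spans_gene"
    if not covered:
        return "no_domain_annotation"
    dom = "".join(cds[3 * i: 3 * i + 3] for i in range(length) if i in covered)
    non = "".join(cds[3 * i: 3 * i + 3] for i in range(length) if i not in covered)
    return count_codons(dom), count_codons(non)


def segment_fop_table(
    sequences: Mapping[str, str],
    annotations: Mapping[str, DomainAnnotation],
    optimal_codons: Iterable[str],
) -> pd.DataFrame:
    """Per-gene domain and nondomain Fop, with exclusion reasons.

    Columns: gene_id, fop_domain, fop_nondomain, excluded (reason or '').
    """
    optimal = set(optimal_codons)
    rows = []
    for gid, cds in sequences.items():
        result = partition_codons(cds, annotations.get(gid))
        if isinstance(result, str):
            rows.append({"gene_id": gid, "fop_domain": math.nan,
                         "fop_nondomain": math.nan, "excluded": result})
        else:
            dom, non = result
            rows.append({"gene_id": gid,
                         "fop_domain": fop(dom, optimal),
                         "fop_nondomain": fop(non, optimal),
                         "excluded": ""})
    return pd.DataFrame(
        rows, columns=["gene_id", "fop_domain", "fop_nondomain", "excluded"]
    )


def _stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def domain_fop_comparison(
    partition: BiasPartition,
    segment_fops: pd.DataFrame,
    *,
    paired: bool = True,
) -> pd.DataFrame:
    """Domain vs nondomain Fop per bias category.

    Each included gene contributes one domain and one nondomain Fop; the
    default test is a two-tailed paired t-test across genes (Welch's
    unpaired test with ``paired=False``).  Categories with fewer than
    two included genes are skipped (nan statistics, ``tested=False``).
    Output mirrors a category x segment summary: mean, SD, n, t, p and
    significance stars at 0.05 / 0.01 / 0.001.
    """
    df = segment_fops[segment_fops["excluded"] == ""].copy()
    df = df.dropna(subset=["fop_domain", "fop_nondomain"])
    df["category"] = df["gene_id"].map(partition.assignments)
    rows = []
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        dom = sub["fop_domain"].to_numpy()
        non = sub["fop_nondomain"].to_numpy()
        ok = len(sub) >= 2
        if ok:
            if paired:
                if np.all(dom == non):
                    t, p = 0.0, 1.0  # identical segments: no difference
                else:
                    t, p = stats.ttest_rel(dom, non)
            else:
                t, p = stats.ttest_ind(dom, non, equal_var=False)
            t, p = float(t), float(p)
        else:
            t, p = math.nan, math.nan
        rows.append({
            "category": cat, "n": len(sub),
            "mean_fop_domain": float(np.mean(dom)) if len(sub) else math.nan,
            "sd_fop_domain": float(np.std(dom, ddof=1)) if len(sub) > 1 else math.nan,
            "mean_fop_nondomain": float(np.mean(non)) if len(sub) else math.nan,
            "sd_fop_nondomain": float(np.std(non, ddof=1)) if len(sub) > 1 else math.nan,
            "t": t, "p": p, "stars": _stars(p) if ok else "",
            "tested": ok,
        })
    return pd.DataFrame(rows)
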