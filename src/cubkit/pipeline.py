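"""End-to-end orchestration of the codon-usage analysis.

Ties the per-module operations into the two entry points users want:
:func:`analyze_sequences` (from a dict of filtered CDSs) and
:func:`analyze_genome` (from FASTA + GFF3, including the noncoding-GC
comparison).  The flow is the study's: metrics → Nc stratification →
pooled optimal codons → CAI/CBI/Fop against the high-bias reference →
neutrality/PR2 diagnostics → selection strength.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .codon_metrics import (
    CodonCountTable,
    cai_weights,
    count_codons,
    metrics_table,
)
from .genome_io import (
    GeneRecord,
    annotate_flanks,
    concatenate_introns,
    filter_cds,
    gc_content,
    load_genome,
)
from .selection_mutation import (
    NeutralityFit,
    nc_deviation,
    neutrality_regression,
    pr2_analysis,
)
from .selection_strength import SelectionStrengthResult, selection_strength
from .stratification import (
    BiasPartition,
    OptimalCodonSet,
    assign_bias_categories,
    category_gc_comparison,
    identify_optimal_codons,
    stop_codon_usage,
)

__all__ = ["GenomeAnalysis", "analyze_sequences", "analyze_genome"]


@dataclass
class GenomeAnalysis:
    """Bundled results of a whole-genome codon-usage analysis."""

    metrics: pd.DataFrame
    partition: BiasPartition
    optimal: OptimalCodonSet
    selection: SelectionStrengthResult
    neutrality: NeutralityFit
    pr2_points: pd.DataFrame
    pr2_counts: dict[str, int]
    stop_usage: pd.DataFrame
    nc_deviation: pd.DataFrame
    frac_below_curve: float
    gc_comparison: pd.DataFrame | None = None
    filter_tally: dict[str, int] | None = None

    @property
    def s_hat(self) -> float:
        return self.selection.s_hat

    def summary(self) -> dict[str, float]:
        """Genome-level headline numbers."""
        return {
            "n_genes": int(len(self.metrics)),
            "mean_Nc": float(self.metrics["Nc"].mean()),
            "mean_GC3s": float(self.metrics["GC3s"].mean()),
            "mean_Fop": float(self.metrics["Fop"].mean()),
            "n_optimal_codons": len(self.optimal.codons),
            "neutrality_slope": self.neutrality.slope,
            "neutrality_r": self.neutrality.r,
            "S_hat": self.s_hat,
            "frac_below_nc_curve": self.frac_below_curve,
        }


def analyze_sequences(
    sequences: Mapping[str, str],
    *,
    p: float = 0.05,
    delta: float = 0.08,
    strict: bool = False,
    continuity: bool = False,
) -> GenomeAnalysis:
    """Run the full analysis on already-filtered CDSs.

    ``p`` is the extreme-percentile used for the bias categories (the
    study used 5–10% per species); ``delta`` the ΔRSCU optimal-codon
    threshold.
    """
    tables = {gid: count_codons(cds) for gid, cds in sequences.items()}
    base = metrics_table(sequences, tables=tables)
    partition = assign_bias_categories(base, p)
    high_pool = CodonCountTable.pool(
        tables[g] for g in partition.genes("high")
    )
    low_pool = CodonCountTable.pool(tables[g] for g in partition.genes("low"))
    optimal = identify_optimal_codons(high_pool, low_pool, delta, strict=strict)
    weights = cai_weights(high_pool)
    metrics = metrics_table(
        sequences, weights=weights, optimal=optimal.codon_set, tables=tables
    )
    sel = selection_strength(high_pool, low_pool, optimal, continuity=continuity)
    fit = neutrality_regression(metrics)
    pr2_points, pr2_counts = pr2_analysis(metrics)
    ncdev, frac_below = nc_deviation(metrics)
    return GenomeAnalysis(
        metrics=metrics,
        partition=partition,
        optimal=optimal,
        selection=sel,
        neutrality=fit,
        pr2_points=pr2_points,
        pr2_counts=pr2_counts,
        stop_usage=stop_codon_usage(high_pool),
        nc_deviation=ncdev,
        frac_below_curve=frac_below,
    )


def noncoding_gc_table(records: list[GeneRecord], metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-gene GC3s plus flank and intron GC for the category comparison."""
    rows = []
    gc3s = dict(zip(metrics["gene_id"], metrics["GC3s"]))
    for rec in records:
        introns = concatenate_introns(rec)
        flank = rec.flank5 + rec.flank3
        rows.append({
            "gene_id": rec.gene_id,
            "GC3s": gc3s.get(rec.gene_id, math.nan),
            "flank_gc": gc_content(flank) if flank else math.nan,
            "intron_gc": gc_content(introns) if introns else math.nan,
        })
    return pd.DataFrame(rows)


def analyze_genome(
    fasta_path: str | Path,
    gff3_path: str | Path,
    *,
    p: float = 0.05,
    delta: float = 0.08,
    flank: int = 200,
    min_length: int = 300,
    strict: bool = False,
) -> GenomeAnalysis:
    """Full pipeline from an assembly and annotation on disk."""
    contigs, records, _skipped = load_genome(fasta_path, gff3_path)
    passed, tally = filter_cds(records, min_length=min_length)
    annotate_flanks(passed, contigs, flank=flank)
    sequences = {rec.gene_id: rec.cds for rec in passed}
    analysis = analyze_sequences(sequences, p=p, delta=delta, strict=strict)
    analysis.filter_tally = dict(tally)
    values = noncoding_gc_table(passed, analysis.metrics)
    analysis.gc_comparison = category_gc_comparison(analysis.partition, values)
    return analysis
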