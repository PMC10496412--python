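"""Per-gene codon-usage metrics.

Implements the classic CodonW-style battery: codon counts, RSCU, the GC
family (GC, GC1, GC2, GC3, GC12, GC3s, third-position base fractions),
Wright's effective number of codons (Nc), the codon adaptation index
(CAI), the codon bias index (CBI) and the frequency of optimal codons
(Fop).

Conventions (documented in docs/methods.md):

* all metrics are computed on the CDS including the initiator ATG and
  excluding the terminal stop codon;
* GC3s is restricted to silent third positions (Met, Trp and stops carry
  no synonymous information and are excluded);
* A3/T3/G3/C3 are computed over *all* sense codons by default (the
  MEGA-style convention used for parity-rule-2 plots); pass
  ``silent_only=True`` for the restricted variant;
* undefined values are returned as ``nan`` rather than raising.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import (
    CODON_TABLE,
    DEGENERACY,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    SYNONYMOUS_FAMILIES,
    is_gc,
)

__all__ = [
    "CodonCountTable",
    "count_codons",
    "rscu",
    "gc_family",
    "effective_number_of_codons",
    "cai",
    "cai_weights",
    "fop",
    "cbi",
    "compute_gene_metrics",
    "metrics_table",
    "METRIC_COLUMNS",
]

#: stable column order of the per-gene metrics table
METRIC_COLUMNS = [
    "gene_id", "length_codons", "GC", "GC1", "GC2", "GC3", "GC12",
    "GC3s", "A3", "T3", "G3", "C3", "Nc", "CAI", "CBI", "Fop",
    "stop_codon",
]

_VALID = frozenset("ACGT")


@dataclass
class CodonCountTable:
    """Codon counts for one gene or a pooled gene category.

    Sense-codon counts and stop-codon counts are kept separately; codons
    containing ambiguity characters are skipped and tallied in
    ``skipped``.
    """

    counts: Counter = field(default_factory=Counter)
    stops: Counter = field(default_factory=Counter)
    skipped: int = 0

    @property
    def total_sense(self) -> int:
        return sum(self.counts.values())

    def family_count(self, aa: str) -> int:
        return sum(self.counts[c] for c in SYNONYMOUS_FAMILIES[aa])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            counts=self.counts + other.counts,
            stops=self.stops + other.stops,
            skipped=self.skipped + other.skipped,
        )

    @staticmethod
    def pool(tables: Iterable["CodonCountTable"]) -> "CodonCountTable":
        pooled = CodonCountTable()
        for t in tables:
            pooled.counts.update(t.counts)
            pooled.stops.update(t.stops)
            pooled.skipped += t.skipped
        return pooled


def count_codons(cds: str) -> CodonCountTable:
    """Frame-0 triplet counts of a coding sequence.

    The CDS length must be divisible by three.  Stop codons (terminal or
    internal) go to the stop table; triplets containing non-ACGT
    characters are skipped and flagged.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    table = CodonCountTable()
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if not _VALID.issuperset(codon):
            table.skipped += 1
        elif codon in STOP_CODONS:
            table.stops[codon] += 1
        else:
            table.counts[codon] += 1
    return table


def rscu(table: CodonCountTable) -> dict[str, float]:
    """Relative synonymous codon usage.

    RSCU(c) = observed count x degeneracy / family total.  Families with
    zero usage yield ``nan`` (missing, not zero); Met, Trp and stops are
    excluded.
    """
    out: dict[str, float] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        total = sum(table.counts[c] for c in fam)
        for c in fam:
            out[c] = table.counts[c] * len(fam) / total if total else math.nan
    return out


def gc_family(
    table: CodonCountTable, *, silent_only_thirds: bool = False
) -> dict[str, float]:
    """GC content by codon position plus third-position base fractions.

    GC1/GC2/GC3 are over all sense codons; GC3s only over silent third
    positions (synonymous-family codons).  A3/T3/G3/C3 default to all
    sense codons; ``silent_only_thirds=True`` restricts them to
    synonymous codons.
    """
    n = table.total_sense
    nan = math.nan
    if n == 0:
        return {k: nan for k in
                ("GC", "GC1", "GC2", "GC3", "GC12", "GC3s",
                 "A3", "T3", "G3", "C3")}
    gc_pos = [0, 0, 0]
    third = Counter()
    third_all = Counter()
    for codon, k in table.counts.items():
        for j in range(3):
            if is_gc(codon[j]):
                gc_pos[j] += k
        third_all[codon[2]] += k
    syn_n = 0
    syn_gc = 0
    for codon in SYNONYMOUS_CODONS:
        k = table.counts[codon]
        syn_n += k
        if is_gc(codon[2]):
            syn_gc += k
        third[codon[2]] += k
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    use = third if silent_only_thirds else third_all
    use_n = sum(use.values())
    return {
        "GC": (gc_pos[0] + gc_pos[1] + gc_pos[2]) / (3 * n),
        "GC1": gc1,
        "GC2": gc2,
        "GC3": gc3,
        "GC12": (gc1 + gc2) / 2,
        "GC3s": syn_gc / syn_n if syn_n else nan,
        "A3": use["A"] / use_n if use_n else nan,
        "T3": use["T"] / use_n if use_n else nan,
        "G3": use["G"] / use_n if use_n else nan,
        "C3": use["C"] / use_n if use_n else nan,
    }


# degeneracy class -> member amino acids, for Wright's estimator
_NC_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _d in DEGENERACY.items():
    _NC_CLASSES.setdefault(_d, ())
    _NC_CLASSES[_d] += (_aa,)


def _family_homozygosity(table: CodonCountTable, aa: str) -> float | None:
    """Wright's F for one family; None when n <= 1 (not estimable)."""
    fam = SYNONYMOUS_FAMILIES[aa]
    n = sum(table.counts[c] for c in fam)
    if n <= 1:
        return None
    sum_p2 = sum((table.counts[c] / n) ** 2 for c in fam)
    f = (n * sum_p2 - 1) / (n - 1)
    # F = 0 (tiny n spread across codons) carries no homozygosity
    # information and would blow up 1/F; treated as not estimable,
    # following Wright's convention
    return f if f > 0 else None


def effective_number_of_codons(table: CodonCountTable) -> float:
    """Wright's Nc from per-family homozygosities.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, with Fd the mean homozygosity of
    the degeneracy-d families that have at least two codons counted.
    A missing 3-fold class (Ile unused or not estimable) is imputed as
    (F2 + F4)/2; a gene missing an entire 2-, 4- or 6-fold class has
    undefined Nc (nan).  Values above the theoretical maximum of 61 are
    capped at 61.
    """
    class_mean: dict[int, float | None] = {}
    for d, aas in _NC_CLASSES.items():
        fs = [f for aa in aas if (f := _family_homozygosity(table, aa)) is not None]
        class_mean[d] = sum(fs) / len(fs) if fs else None
    if class_mean[3] is None and class_mean[2] is not None and class_mean[4] is not None:
        class_mean[3] = (class_mean[2] + class_mean[4]) / 2
    if any(class_mean[d] is None or class_mean[d] <= 0 for d in (2, 3, 4, 6)):
        return math.nan
    nc = (2 + 9 / class_mean[2] + 1 / class_mean[3]
          + 5 / class_mean[4] + 3 / class_mean[6])
    return min(nc, 61.0)


def cai_weights(reference: CodonCountTable) -> dict[str, float]:
    """Relative adaptiveness weights from a highly expressed reference set.

    w(c) = RSCU_ref(c) / max family RSCU_ref = count(c) / max family
    count.  Codons unused in the reference get the conventional floor of
    0.01; families entirely absent from the reference get weight 1 for
    every member (no information).
    """
    weights: dict[str, float] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        mx = max(reference.counts[c] for c in fam)
        for c in fam:
            if mx == 0:
                weights[c] = 1.0
            else:
                weights[c] = max(reference.counts[c] / mx, 0.01)
    return weights


def cai(table: CodonCountTable, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over synonymous codons."""
    log_sum = 0.0
    n = 0
    for codon in SYNONYMOUS_CODONS:
        k = table.counts[codon]
        if k:
            log_sum += k * math.log(weights[codon])
            n += k
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def fop(table: CodonCountTable, optimal: Iterable[str]) -> float:
    """Frequency of optimal codons among all synonymous codons."""
    optimal = set(optimal)
    n_syn = sum(table.counts[c] for c in SYNONYMOUS_CODONS)
    if n_syn == 0:
        return math.nan
    n_opt = sum(table.counts[c] for c in optimal if c in SYNONYMOUS_CODONS)
    return n_opt / n_syn


def cbi(table: CodonCountTable, optimal: Iterable[str]) -> float:
    """Codon bias index.

    CBI = (N_opt - N_ran) / (N_tot - N_ran) over the families that
    contain at least one optimal codon, with N_ran the usage expected
    under uniform synonymous choice.  1 = exclusive optimal usage,
    0 = random, negative = optimal codons avoided.
    """
    optimal = set(optimal)
    n_opt = n_tot = 0
    n_ran = 0.0
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        fam_opt = [c for c in fam if c in optimal]
        if not fam_opt:
            continue
        fam_n = sum(table.counts[c] for c in fam)
        n_tot += fam_n
        n_opt += sum(table.counts[c] for c in fam_opt)
        n_ran += fam_n * len(fam_opt) / len(fam)
    if n_tot - n_ran == 0:
        return math.nan
    return (n_opt - n_ran) / (n_tot - n_ran)


def compute_gene_metrics(
    gene_id: str,
    cds: str,
    *,
    weights: Mapping[str, float] | None = None,
    optimal: Iterable[str] | None = None,
    table: CodonCountTable | None = None,
) -> dict[str, object]:
    """One metrics-table row for a CDS.

    CAI requires ``weights``; CBI and Fop require ``optimal``; omitted
    references yield nan for the dependent metrics.  A precomputed count
    table may be passed to avoid recounting.
    """
    if table is None:
        table = count_codons(cds)
    row: dict[str, object] = {
        "gene_id": gene_id,
        "length_codons": len(cds) // 3,
    }
    row.update(gc_family(table))
    row["Nc"] = effective_number_of_codons(table)
    row["CAI"] = cai(table, weights) if weights is not None else math.nan
    if optimal is not None:
        opt_codons = list(optimal)
        row["CBI"] = cbi(table, opt_codons)
        row["Fop"] = fop(table, opt_codons)
    else:
        row["CBI"] = math.nan
        row["Fop"] = math.nan
    if table.stops:
        row["stop_codon"] = table.stops.most_common(1)[0][0]
    else:
        row["stop_codon"] = ""
    return row


def metrics_table(
    sequences: Mapping[str, str],
    *,
    weights: Mapping[str, float] | None = None,
    optimal: Iterable[str] | None = None,
    tables: Mapping[str, CodonCountTable] | None = None,
) -> pd.DataFrame:
    """Per-gene metrics for a set of CDSs, in stable column order."""
    optimal = list(optimal) if optimal is not None else None
    rows = [
        compute_gene_metrics(
            gid, cds, weights=weights, optimal=optimal,
            table=tables.get(gid) if tables is not None else None,
        )
        for gid, cds in sequences.items()
    ]
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return df.astype({c: float for c in METRIC_COLUMNS
                      if c not in ("gene_id", "stop_codon", "length_codons")})
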