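"""Genome parsing: FASTA + GFF3 to filtered, spliced coding sequences.

A GFF3 gene/mRNA/CDS hierarchy is resolved into one candidate
:class:`GeneRecord` per mRNA (spliced, reverse-complemented on the minus
strand), which is then screened with the seven CDS filters:

1. length a multiple of three,
2. ATG start codon,
3. TAA/TAG/TGA stop codon,
4. no internal (premature) stop codon,
5. length greater than 300 nt,
6. one longest transcript per gene (isoform/duplicate removal),
7. no pseudogenes and no ambiguity characters in the CDS (the
   sequence-intrinsic proxy for poor sequencing quality).

Coordinates are 0-based half-open internally; GFF3's 1-based closed
intervals are converted at the boundary.  Flanking DNA (up to 200 bp per
side, truncated at contig ends and at neighbouring genes) and
concatenated introns are extracted for the noncoding-GC analyses.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS, reverse_complement

__all__ = [
    "ContigSet",
    "GeneRecord",
    "load_genome",
    "filter_cds",
    "extract_flanks",
    "annotate_flanks",
    "concatenate_introns",
    "gc_content",
    "read_fasta",
    "write_fasta",
    "FILTER_RULES",
]

#: rule names in the order they are checked; a failing record reports the
#: first rule it violates
FILTER_RULES = (
    "pseudogene",
    "not_multiple_of_three",
    "bad_start_codon",
    "bad_stop_codon",
    "internal_stop",
    "too_short",
    "ambiguous_bases",
    "not_longest_isoform",
)

_VALID = frozenset("ACGT")


@dataclass
class ContigSet:
    """Nucleotide sequences of an assembly, keyed by contig id."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"contig {cid!r} is empty")

    def __getitem__(self, cid: str) -> str:
        return self.sequences[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.sequences

    def length(self, cid: str) -> int:
        return len(self.sequences[cid])

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class GeneRecord:
    """One mRNA's spliced CDS with its introns, flanks and provenance."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # ascending contig coords, 0-based half-open
    cds: str  # coding strand, 5'->3'
    introns: list[str] = field(default_factory=list)  # coding orientation
    flank5: str = ""
    flank3: str = ""
    pseudo: bool = False
    status: str = "unfiltered"  # 'pass' | 'fail:<rule>' | 'unfiltered'

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return len(self.cds)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def _is_pseudo(*features: gffutils.Feature) -> bool:
    for f in features:
        if f is None:
            continue
        if f.featuretype in ("pseudogene", "pseudogenic_transcript"):
            return True
        attrs = {k.lower(): v for k, v in f.attributes.items()}
        if "pseudo" in attrs and str(attrs["pseudo"][0]).lower() in ("true", "1", ""):
            return True
    return False


def load_genome(
    fasta_path: str | Path, gff3_path: str | Path
) -> tuple[ContigSet, list[GeneRecord], dict[str, str]]:
    """Parse an assembly and its annotation into candidate gene records.

    Returns ``(contigs, records, skipped)`` where ``records`` holds one
    candidate per mRNA (spliced, coding-strand orientation) and
    ``skipped`` maps mRNA ids to the reason a gene model was rejected
    outright (CDS outside contig bounds, or a first-segment phase other
    than 0 — the ATG-anchored frame assumption).
    """
    contigs = ContigSet(read_fasta(fasta_path))
    try:
        db = gffutils.create_db(
            str(gff3_path), ":memory:",
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"unparseable GFF3 {gff3_path}: {exc}") from exc

    records: list[GeneRecord] = []
    skipped: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        parents = list(db.parents(mrna, featuretype=("gene", "pseudogene")))
        gene = parents[0] if parents else None
        gid = gene.id if gene is not None else tid
        cds_feats = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds_feats:
            skipped[tid] = "no CDS features"
            continue
        if mrna.seqid not in contigs:
            skipped[tid] = f"contig {mrna.seqid} not in FASTA"
            continue
        contig_seq = contigs[mrna.seqid]
        exons = [(f.start - 1, f.end) for f in cds_feats]  # to 0-based half-open
        if exons[0][0] < 0 or exons[-1][1] > len(contig_seq):
            skipped[tid] = "CDS interval outside contig bounds"
            continue
        strand = mrna.strand if mrna.strand in ("+", "-") else "+"
        first = cds_feats[0] if strand == "+" else cds_feats[-1]
        if first.frame not in (".", "0", None):
            skipped[tid] = f"first CDS segment phase {first.frame} != 0"
            continue
        pieces = [contig_seq[s:e] for s, e in exons]
        spliced = "".join(pieces)
        intron_seqs = [
            contig_seq[exons[i][1]: exons[i + 1][0]]
            for i in range(len(exons) - 1)
        ]
        if strand == "-":
            spliced = reverse_complement(spliced)
            intron_seqs = [reverse_complement(s) for s in reversed(intron_seqs)]
        records.append(
            GeneRecord(
                gene_id=gid,
                transcript_id=tid,
                contig=mrna.seqid,
                strand=strand,
                exons=exons,
                cds=spliced,
                introns=intron_seqs,
                pseudo=_is_pseudo(gene, mrna),
            )
        )
    return contigs, records, skipped


def _sequence_rule(record: GeneRecord, min_length: int) -> str | None:
    """First violated sequence-level rule, or None."""
    cds = record.cds
    if record.pseudo:
        return "pseudogene"
    if len(cds) % 3 != 0:
        return "not_multiple_of_three"
    if cds[:3] != "ATG":
        return "bad_start_codon"
    if cds[-3:] not in STOP_CODONS:
        return "bad_stop_codon"
    for i in range(3, len(cds) - 3, 3):
        if cds[i: i + 3] in STOP_CODONS:
            return "internal_stop"
    if len(cds) <= min_length:
        return "too_short"
    if not _VALID.issuperset(cds):
        return "ambiguous_bases"
    return None


def filter_cds(
    records: Sequence[GeneRecord], *, min_length: int = 300
) -> tuple[list[GeneRecord], Counter]:
    """Apply the seven CDS filters.

    Returns the pass set and a per-rule rejection tally.  Each record's
    ``status`` is updated in place to ``'pass'`` or ``'fail:<rule>'``
    (the first violated rule).  The longest transcript per gene is kept
    among records passing the sequence rules; ties break on the
    lexicographically smallest transcript id.
    """
    tally: Counter = Counter()
    survivors: list[GeneRecord] = []
    for rec in records:
        rule = _sequence_rule(rec, min_length)
        if rule is not None:
            rec.status = f"fail:{rule}"
            tally[rule] += 1
        else:
            survivors.append(rec)
    best: dict[str, GeneRecord] = {}
    for rec in survivors:
        cur = best.get(rec.gene_id)
        if cur is None or (-rec.length, rec.transcript_id) < (-cur.length, cur.transcript_id):
            best[rec.gene_id] = rec
    passed: list[GeneRecord] = []
    for rec in survivors:
        if best[rec.gene_id] is rec:
            rec.status = "pass"
            passed.append(rec)
        else:
            rec.status = "fail:not_longest_isoform"
            tally["not_longest_isoform"] += 1
    return passed, tally


def extract_flanks(
    record: GeneRecord,
    contigs: ContigSet,
    neighbor_bounds: Iterable[tuple[int, int]],
    *,
    flank: int = 200,
) -> tuple[str, str]:
    """Flanking DNA up to ``flank`` bp per side, in coding orientation.

    Each flank is truncated at the contig end and at the nearest
    neighbouring gene interval; a gene abutting its neighbour yields an
    empty flank.
    """
    start, end = record.span
    contig_len = contigs.length(record.contig)
    left_limit = 0
    right_limit = contig_len
    for n_start, n_end in neighbor_bounds:
        if n_start < start:
            left_limit = max(left_limit, min(n_end, start))
        if n_end > end:
            right_limit = min(right_limit, max(n_start, end))
    left_len = min(flank, start - left_limit)
    right_len = min(flank, right_limit - end)
    left = contigs[record.contig][start - left_len: start] if left_len > 0 else ""
    right = contigs[record.contig][end: end + right_len] if right_len > 0 else ""
    if record.strand == "-":
        return reverse_complement(right), reverse_complement(left)
    return left, right


def annotate_flanks(
    records: Sequence[GeneRecord], contigs: ContigSet, *, flank: int = 200
) -> None:
    """Fill ``flank5``/``flank3`` for every record, respecting neighbours."""
    by_contig: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_contig.setdefault(rec.contig, []).append(rec)
    for contig_recs in by_contig.values():
        spans = [r.span for r in contig_recs]
        for rec in contig_recs:
            neighbors = [s for s, r in zip(spans, contig_recs) if r is not rec]
            rec.flank5, rec.flank3 = extract_flanks(
                rec, contigs, neighbors, flank=flank
            )


def concatenate_introns(record: GeneRecord) -> str | None:
    """All introns of a gene joined 5'->3'; None for intronless genes.

    Intronless genes are excluded from intron-GC statistics downstream.
    """
    if not record.introns:
        return None
    return "".join(record.introns)


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous bases; nan for empty sequences."""
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / n
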