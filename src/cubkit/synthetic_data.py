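"""Synthetic genomes with known codon-usage ground truth.

Generates multi-gene contigs (FASTA + GFF3) together with a tRNA
prediction file, a domain-interval table and a truth table, so the whole
pipeline — extraction, filtering, metrics, stratification, optimal-codon
calling, selection strength, tRNA matching, domain Fop — runs offline
with a known answer.

The gene model
--------------

Each gene draws a mutational GC parameter ``m`` and a selection
intensity ``w`` (by expression class).  Codons are drawn from a mixture:
with probability ``w`` the codon is the designated optimal codon of the
(already drawn) amino acid — translational selection acts on the
synonymous choice, leaving the protein sequence alone — and otherwise
from a GC-parameterised mutational null.

The mutational null treats regional mutation pressure as acting on all
three codon positions with the same GC parameter: each codon draws one
GC "coin" per position, the amino acid is chosen uniformly among those
whose codon prefix matches the first two coins (amino-acid-preserving
where degeneracy allows), and the silent third base matches the third
coin.  The coin *composition* at positions 1-2 is pinned at
``round(m*n)`` per gene (random arrangement, deterministic count), so
realised GC12 equals the mutational parameter up to rounding and the
neutrality regression of GC3 on GC12 — whose x-axis would otherwise be
a binomially blurred copy of the parameter — is centred on slope 1
under pure mutation.  The silent third position keeps free Bernoulli
coins: within-family usage is exchangeable under codon relabelling, so
a neutral genome carries no selection signal, and Nc tracks Wright's
expectation.  Met and Trp are excluded from the body draw by default
(their forced third-position G would leak a non-mutational constant
into GC3); they carry no synonymous-usage information, and
``include_met_trp=True`` restores them.

Introns, flanking and intergenic DNA get GC contents coupled to the
gene's ``m`` with a configurable coefficient, emulating noncoding GC
tracking coding GC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import (
    SYNONYMOUS_FAMILIES,
    is_gc,
    reverse_complement,
    translate_codon,
    AA_THREE_LETTER,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticGenome",
    "generate_genome",
    "generate_trna_file",
    "DEFAULT_OPTIMAL_CODONS",
    "neutral_spec",
    "mutation_only_spec",
    "strong_selection_spec",
    "selection_gradient_spec",
    "red_algal_spec",
]

#: designated optimal codons, one per degenerate family; G/C-ending
#: (no A-ending), mirroring the red-algal pattern
DEFAULT_OPTIMAL_CODONS: dict[str, str] = {
    "F": "TTC", "Y": "TAC", "H": "CAC", "Q": "CAG", "N": "AAC",
    "K": "AAG", "D": "GAC", "E": "GAG", "C": "TGC", "I": "ATC",
    "V": "GTG", "T": "ACG", "A": "GCC", "P": "CCG", "G": "GGC",
    "L": "CTG", "S": "AGC", "R": "CGC",
}


@dataclass
class SyntheticSpec:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    n_genes: int = 500
    # gene length in codons (incl. start and stop): clipped lognormal
    length_log_mean: float = math.log(400.0)
    length_log_sigma: float = 0.35
    min_length_codons: int = 110
    max_length_codons: int = 2000
    # per-gene mutational GC parameter ~ Uniform(gc_low, gc_high)
    gc_low: float = 0.30
    gc_high: float = 0.85
    # expression classes (high, mid, low): fractions sum to 1,
    # intensities are the optimal-codon mixture weights in [0, 1]
    class_fractions: tuple[float, float, float] = (0.10, 0.80, 0.10)
    class_intensities: tuple[float, float, float] = (0.45, 0.10, 0.0)
    optimal_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OPTIMAL_CODONS)
    )
    include_met_trp: bool = False
    stop_probs: dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.6, "TAG": 0.2, "TGA": 0.2}
    )
    # intron model
    intron_mean: float = 1.5  # Poisson count per gene
    intron_length_range: tuple[int, int] = (50, 300)
    noncoding_gc_coupling: float = 0.8
    noncoding_gc_noise: float = 0.03
    # contig layout
    intergenic_range: tuple[int, int] = (150, 1000)
    genes_per_contig: int = 25
    minus_strand_fraction: float = 0.5
    # tRNA gene complement: anticodon (5'->3' DNA) -> copy number;
    # None derives Watson-Crick partners of the optimal codons
    trna_complement: dict[str, int] | None = None
    include_sec_trna: bool = False
    n_pseudo_trna: int = 0
    # domains
    domain_prob: float = 0.9
    domain_fraction: float = 0.5
    domain_intensity: float | None = None  # override w inside domains

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if any(w < 0 or w > 1 for w in self.class_intensities):
            raise ValueError("intensities must be in [0, 1]")
        if abs(sum(self.stop_probs.values()) - 1.0) > 1e-9:
            raise ValueError("stop probabilities must sum to 1")


# ---------------------------------------------------------------------------
# codon-drawing tables

def _pattern(prefix: str) -> tuple[int, int]:
    return int(is_gc(prefix[0])), int(is_gc(prefix[1]))


def _build_distributions(
    optimal: dict[str, str], include_met_trp: bool
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-coin-state codon distributions for the mutational null.

    Index ``4*c1 + 2*c2 + c3`` (cj = GC coin of codon position j) maps
    to (codons, cumulative probs, optimal replacement): the amino acid
    is uniform among those whose codon prefix matches (c1, c2), the
    silent third base uniform among the family endings in c3's GC class
    (falling back to all endings when the family is one-sided, e.g. the
    forced G of Met/Trp).  The replacement array holds each codon's
    amino acid's designated optimal codon.
    """
    families: dict[str, tuple[str, ...]] = dict(SYNONYMOUS_FAMILIES)
    if include_met_trp:
        families["M"] = ("ATG",)
        families["W"] = ("TGG",)
    prefixes = {
        aa: sorted({c[:2] for c in fam}) for aa, fam in families.items()
    }
    endings = {
        (aa, p): sorted(c[2] for c in fam if c[:2] == p)
        for aa, fam in families.items() for p in prefixes[aa]
    }
    dists = []
    for c1 in (0, 1):
        for c2 in (0, 1):
            want = (c1, c2)
            group = sorted(
                aa for aa in families if any(_pattern(p) == want for p in prefixes[aa])
            )
            for c3 in (0, 1):
                probs: dict[str, float] = {}
                for aa in group:
                    matching = [p for p in prefixes[aa] if _pattern(p) == want]
                    for p in matching:
                        ends = endings[(aa, p)]
                        class_ends = [b for b in ends if is_gc(b) == bool(c3)]
                        use = class_ends or ends  # one-sided family fallback
                        for b in use:
                            codon = p + b
                            probs[codon] = probs.get(codon, 0.0) + (
                                1.0 / len(group) / len(matching) / len(use)
                            )
                codons = np.array(sorted(probs), dtype="<U3")
                pvec = np.array([probs[c] for c in codons])
                cum = np.cumsum(pvec)
                cum[-1] = 1.0
                opts = np.array(
                    [optimal.get(translate_codon(c), c) for c in codons], dtype="<U3"
                )
                dists.append((codons, cum, opts))
    return dists


def _pinned_coins(rng: np.random.Generator, n: int, m: float) -> np.ndarray:
    """n binary GC coins whose composition is pinned at round(m*n).

    The arrangement is random but the per-gene count is deterministic,
    so a gene's realised positional GC equals its mutational parameter
    up to rounding — regression diagnostics then see the parameter
    itself rather than a binomially blurred copy.
    """
    k = int(round(m * n))
    return (rng.permutation(n) < k).astype(int)


def _draw_body(
    rng: np.random.Generator,
    n: int,
    m: float,
    w: np.ndarray,
    dists,
) -> np.ndarray:
    """n body codons for one gene (mutational GC m, per-codon weight w).

    Positions 1-2 use composition-pinned coins (realised GC12 = m up to
    rounding, removing errors-in-variables attenuation from the
    neutrality regression, whose x-axis is GC12); the silent third
    position uses free Bernoulli coins, so within-family usage is
    exactly exchangeable under relabelling — a neutral genome carries
    no spurious selection signal.
    """
    c1 = _pinned_coins(rng, n, m)
    c2 = _pinned_coins(rng, n, m)
    c3 = (rng.random(n) < m).astype(int)
    u = rng.random(n)
    u_sel = rng.random(n)
    state = 4 * c1 + 2 * c2 + c3
    out = np.empty(n, dtype="<U3")
    for k in range(8):
        mask = state == k
        if not mask.any():
            continue
        codons, cum, opts = dists[k]
        idx = np.searchsorted(cum, u[mask], side="right").clip(max=len(codons) - 1)
        chosen = codons[idx]
        selected = u_sel[mask] < w[mask]
        out[mask] = np.where(selected, opts[idx], chosen)
    return out


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    strong = rng.random(length) < gc
    half = rng.random(length) < 0.5
    bases = np.where(strong, np.where(half, "G", "C"), np.where(half, "A", "T"))
    return "".join(bases)


def _noncoding_gc(rng: np.random.Generator, spec: SyntheticSpec, m: float) -> float:
    gc = 0.5 + spec.noncoding_gc_coupling * (m - 0.5)
    gc += rng.normal(0.0, spec.noncoding_gc_noise)
    return float(np.clip(gc, 0.02, 0.98))


# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """In-memory result of :func:`generate_genome`."""

    contigs: dict[str, str]
    gff3: str
    truth: pd.DataFrame
    trna_text: str
    domains: pd.DataFrame
    sequences: dict[str, str]  # gene id -> spliced CDS (ground truth)
    spec: SyntheticSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, tRNA scan, domain and truth files."""
        from .genome_io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "trna": outdir / "trnascan.txt",
            "domains": outdir / "domains.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(paths["fasta"], self.contigs)
        paths["gff3"].write_text(self.gff3)
        paths["trna"].write_text(self.trna_text)
        self.domains.to_csv(paths["domains"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Generate a genome per ``spec``; same seed, same bytes out."""
    rng = np.random.default_rng(spec.seed)
    dists = _build_distributions(spec.optimal_codons, spec.include_met_trp)
    stops = list(spec.stop_probs)
    stop_p = np.array([spec.stop_probs[s] for s in stops])
    class_names = ("high", "mid", "low")

    n = spec.n_genes
    lengths = np.exp(
        rng.normal(spec.length_log_mean, spec.length_log_sigma, size=n)
    ).astype(int)
    lengths = np.clip(lengths, spec.min_length_codons, spec.max_length_codons)
    ms = rng.uniform(spec.gc_low, spec.gc_high, size=n)
    classes = rng.choice(3, size=n, p=np.asarray(spec.class_fractions))
    strands = np.where(rng.random(n) < spec.minus_strand_fraction, "-", "+")

    truth_rows = []
    domain_rows = []
    gff_lines = ["##gff-version 3"]
    contigs: dict[str, str] = {}
    sequences: dict[str, str] = {}
    spacers: list[tuple[str, int, int]] = []  # intergenic room for tRNAs

    contig_parts: list[str] = []
    contig_genes = 0
    contig_id = "ctg001"
    contig_idx = 1
    pos = 0

    def _flush_contig() -> None:
        nonlocal contig_parts, contig_genes, contig_id, contig_idx, pos
        if contig_parts:
            contigs[contig_id] = "".join(contig_parts)
        contig_idx += 1
        contig_id = f"ctg{contig_idx:03d}"
        contig_parts = []
        contig_genes = 0
        pos = 0

    for gi in range(n):
        gid = f"g{gi + 1:05d}"
        L = int(lengths[gi])
        m = float(ms[gi])
        cls = int(classes[gi])
        w_base = float(spec.class_intensities[cls])
        n_body = L - 2

        # domain interval (codon units over the whole gene, start codon = 0)
        dom_interval: tuple[int, int] | None = None
        if rng.random() < spec.domain_prob:
            dlen = max(1, min(int(round(spec.domain_fraction * n_body)), n_body - 1))
            dstart = 1 + int(rng.integers(0, n_body - dlen + 1))
            dom_interval = (dstart, dstart + dlen)
            domain_rows.append({
                "gene_id": gid, "start_codon": dstart,
                "end_codon": dstart + dlen,
                "domain_accession": f"SYNDOM{gi + 1:05d}",
            })

        w = np.full(n_body, w_base)
        if spec.domain_intensity is not None and dom_interval is not None:
            ds, de = dom_interval
            w[max(ds - 1, 0): de - 1] = spec.domain_intensity

        body = _draw_body(rng, n_body, m, w, dists)
        stop = stops[int(rng.choice(len(stops), p=stop_p))]
        cds = "ATG" + "".join(body) + stop
        sequences[gid] = cds

        # introns: breakpoints inside the CDS, coding orientation
        n_introns = int(rng.poisson(spec.intron_mean))
        n_introns = min(n_introns, (len(cds) - 6) // 2)
        cuts = sorted(
            int(c) for c in rng.choice(
                np.arange(3, len(cds) - 3), size=n_introns, replace=False
            )
        ) if n_introns else []
        exon_segments = []
        prev = 0
        for cut in cuts:
            exon_segments.append((prev, cut))
            prev = cut
        exon_segments.append((prev, len(cds)))
        intron_seqs = [
            _random_seq(
                rng,
                int(rng.integers(*spec.intron_length_range)),
                _noncoding_gc(rng, spec, m),
            )
            for _ in cuts
        ]

        # genomic gene sequence in transcript orientation
        parts = []
        tx_exons = []  # transcript-orientation genomic offsets within gene
        offset = 0
        for i, (a, b) in enumerate(exon_segments):
            parts.append(cds[a:b])
            tx_exons.append((offset, offset + (b - a)))
            offset += b - a
            if i < len(intron_seqs):
                parts.append(intron_seqs[i])
                offset += len(intron_seqs[i])
        gene_seq = "".join(parts)
        gene_len = len(gene_seq)

        # leading spacer
        spacer_len = int(rng.integers(*spec.intergenic_range))
        spacer_gc = _noncoding_gc(rng, spec, m)
        spacer = _random_seq(rng, spacer_len, spacer_gc)
        contig_parts.append(spacer)
        spacers.append((contig_id, pos, pos + spacer_len))
        pos += spacer_len

        strand = strands[gi]
        g_start = pos  # 0-based
        if strand == "+":
            contig_parts.append(gene_seq)
            genomic_exons = [(g_start + a, g_start + b) for a, b in tx_exons]
        else:
            contig_parts.append(reverse_complement(gene_seq))
            genomic_exons = [
                (g_start + gene_len - b, g_start + gene_len - a)
                for a, b in tx_exons
            ]
            genomic_exons.sort()
        pos += gene_len

        # GFF3 (1-based closed); phases follow the transcript order
        tid = f"{gid}.t1"
        g_end = g_start + gene_len
        gff_lines.append(
            f"{contig_id}\tcubkit_sim\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{contig_id}\tcubkit_sim\tmRNA\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        phases = []
        cum = 0
        for a, b in exon_segments:
            phases.append((3 - cum % 3) % 3)
            cum += b - a
        ordered = (
            list(zip(genomic_exons, phases))
            if strand == "+"
            else list(zip(genomic_exons, reversed(phases)))
        )
        for (s, e), ph in ordered:
            gff_lines.append(
                f"{contig_id}\tcubkit_sim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{ph}\t"
                f"ID={tid}.cds;Parent={tid}"
            )

        truth_rows.append({
            "gene_id": gid, "contig": contig_id, "strand": strand,
            "class": class_names[cls], "intensity": w_base,
            "mutational_gc": m, "length_codons": L,
            "n_introns": len(intron_seqs),
            "start": g_start, "end": g_end,
        })

        contig_genes += 1
        if contig_genes >= spec.genes_per_contig:
            # trailing spacer, then start a new contig
            tail = _random_seq(
                rng, int(rng.integers(*spec.intergenic_range)),
                _noncoding_gc(rng, spec, m),
            )
            spacers.append((contig_id, pos, pos + len(tail)))
            contig_parts.append(tail)
            pos += len(tail)
            _flush_contig()
    if contig_parts:
        tail = _random_seq(rng, int(rng.integers(*spec.intergenic_range)), 0.5)
        spacers.append((contig_id, pos, pos + len(tail)))
        contig_parts.append(tail)
        contigs[contig_id] = "".join(contig_parts)

    trna_text = _emit_trna(rng, spec, spacers)

    truth = pd.DataFrame(truth_rows)
    domains = pd.DataFrame(
        domain_rows,
        columns=["gene_id", "start_codon", "end_codon", "domain_accession"],
    )
    return SyntheticGenome(
        contigs=contigs,
        gff3="\n".join(gff_lines) + "\n",
        truth=truth,
        trna_text=trna_text,
        domains=domains,
        sequences=sequences,
        spec=spec,
    )


_TRNA_LEN = 72

_TRNA_HEADER = (
    "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
    "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\t----\n"
)


def _default_complement(spec: SyntheticSpec) -> dict[str, int]:
    """Watson-Crick anticodons of the designated optimal codons, 2-4 copies."""
    comp = {}
    for i, (aa, codon) in enumerate(sorted(spec.optimal_codons.items())):
        comp[reverse_complement(codon)] = 2 + (i % 3)
    return comp


def _emit_trna(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    spacers: list[tuple[str, int, int]],
) -> str:
    complement = spec.trna_complement
    if complement is None:
        complement = _default_complement(spec)
    rows = []
    slots = [s for s in spacers if s[2] - s[1] >= _TRNA_LEN + 10]
    slot_i = 0
    counters: dict[str, int] = {}

    def _place() -> tuple[str, int, int]:
        nonlocal slot_i
        if slot_i >= len(slots):
            raise ValueError("more tRNA genes than available intergenic space")
        contig, s, e = slots[slot_i]
        slot_i += 1
        begin = s + 5
        return contig, begin + 1, begin + _TRNA_LEN  # 1-based inclusive

    for anticodon in sorted(complement):
        aa = translate_codon(reverse_complement(anticodon))
        isotype = AA_THREE_LETTER.get(aa, "Und")
        for _ in range(complement[anticodon]):
            contig, b, e = _place()
            counters[contig] = counters.get(contig, 0) + 1
            score = 50.0 + float(rng.random()) * 40.0
            rows.append(
                f"{contig}\t{counters[contig]}\t{b}\t{e}\t{isotype}\t{anticodon}"
                f"\t0\t0\t{score:.1f}\t"
            )
    if spec.include_sec_trna:
        contig, b, e = _place()
        counters[contig] = counters.get(contig, 0) + 1
        rows.append(f"{contig}\t{counters[contig]}\t{b}\t{e}\tSeC\tTCA\t0\t0\t95.0\t")
    for _ in range(spec.n_pseudo_trna):
        contig, b, e = _place()
        counters[contig] = counters.get(contig, 0) + 1
        rows.append(f"{contig}\t{counters[contig]}\t{b}\t{e}\tPseudo\tGCC\t0\t0\t21.0\tpseudo")
    return _TRNA_HEADER + "\n".join(rows) + ("\n" if rows else "")


def generate_trna_file(spec: SyntheticSpec) -> str:
    """tRNAscan-SE-format text for ``spec`` (via a full genome layout)."""
    return generate_genome(spec).trna_text


# ---------------------------------------------------------------------------
# preset study conditions

def neutral_spec(n_genes: int = 500, seed: int = 0, **kw) -> SyntheticSpec:
    """No selection, flat mutational GC of 0.5 — the null condition."""
    return SyntheticSpec(
        seed=seed, n_genes=n_genes,
        class_intensities=(0.0, 0.0, 0.0),
        gc_low=0.5, gc_high=0.5, **kw,
    )


def mutation_only_spec(n_genes: int = 2000, seed: int = 0, **kw) -> SyntheticSpec:
    """Pure mutation: per-gene GC spans the red-algal range, no selection."""
    return SyntheticSpec(
        seed=seed, n_genes=n_genes,
        class_intensities=(0.0, 0.0, 0.0), **kw,
    )


def strong_selection_spec(n_genes: int = 2000, seed: int = 0, **kw) -> SyntheticSpec:
    """Strong genome-wide translational selection toward the optimal set."""
    return SyntheticSpec(
        seed=seed, n_genes=n_genes,
        class_intensities=(0.95, 0.95, 0.95), **kw,
    )


def selection_gradient_spec(
    high_intensity: float, n_genes: int = 1000, seed: int = 0, **kw
) -> SyntheticSpec:
    """Expression-linked selection at a fixed mutational background.

    A single-factor experiment: mutational GC is held flat at 0.5 so
    that the Nc ranking reflects translational selection alone and a
    measured Ŝ responds only to ``high_intensity``.
    """
    kw.setdefault("gc_low", 0.5)
    kw.setdefault("gc_high", 0.5)
    return SyntheticSpec(
        seed=seed, n_genes=n_genes,
        class_intensities=(high_intensity, high_intensity / 4.0, 0.0), **kw,
    )


def red_algal_spec(n_genes: int = 800, seed: int = 0, **kw) -> SyntheticSpec:
    """One species-like genome: within-genome GC3s spread and selection
    contrasts of the magnitude seen in red-algal nuclear genomes (a
    narrower mutational range than the cross-species 0.3–0.85 span).
    """
    kw.setdefault("gc_low", 0.45)
    kw.setdefault("gc_high", 0.75)
    return SyntheticSpec(seed=seed, n_genes=n_genes, **kw)
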