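"""CDS extraction, splicing, the seven filters, flanks and introns."""

from __future__ import annotations

import pytest

from cubkit.genetic_code import reverse_complement
from cubkit.genome_io import (
    ContigSet,
    GeneRecord,
    concatenate_introns,
    extract_flanks,
    filter_cds,
    load_genome,
    read_fasta,
    write_fasta,
)
from cubkit.synthetic_data import SyntheticSpec, generate_genome


def _single_exon_gff(start: int, end: int, strand: str = "+") -> str:
    return f"""\
chr1\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID=geneA
chr1\ttest\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID=mrnaA;Parent=geneA
chr1\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID=cdsA;Parent=mrnaA
"""


def _make_cds(n_codons_body: int) -> str:
    return "ATG" + "GCT" * n_codons_body + "TAA"


class TestLoadGenome:
    def test_forward_single_exon_identity(self, toy_genome_writer):
        cds = _make_cds(99)  # 303 bp
        contig = "T" * 50 + cds + "T" * 50
        fasta, gff = toy_genome_writer(contig, _single_exon_gff(51, 50 + len(cds)))
        _, records, skipped = load_genome(fasta, gff)
        assert not skipped
        assert records[0].cds == cds
        assert records[0].strand == "+"

    def test_minus_strand_reverse_complement(self, toy_genome_writer):
        cds = _make_cds(99)
        contig = "T" * 50 + reverse_complement(cds) + "T" * 50
        fasta, gff = toy_genome_writer(contig, _single_exon_gff(51, 50 + len(cds), "-"))
        _, records, _ = load_genome(fasta, gff)
        assert records[0].cds == cds

    def test_two_exon_gene_splices_out_intron(self, toy_genome_writer):
        cds = _make_cds(99)
        intron = "G" * 50
        contig = "T" * 10 + cds[:150] + intron + cds[150:] + "T" * 10
        gff = f"""\
chr1\ttest\tgene\t11\t{10 + len(cds) + 50}\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t11\t{10 + len(cds) + 50}\t.\t+\t.\tID=mrnaA;Parent=geneA
chr1\ttest\tCDS\t11\t160\t.\t+\t0\tID=c1;Parent=mrnaA
chr1\ttest\tCDS\t211\t{10 + len(cds) + 50}\t.\t+\t0\tID=c2;Parent=mrnaA
"""
        fasta, gpath = toy_genome_writer(contig, gff)
        _, records, _ = load_genome(fasta, gpath)
        rec = records[0]
        assert rec.cds == cds
        assert rec.introns == [intron]

    def test_out_of_bounds_cds_rejected_with_reason(self, toy_genome_writer):
        fasta, gff = toy_genome_writer("ACGT" * 30, _single_exon_gff(100, 500))
        _, records, skipped = load_genome(fasta, gff)
        assert not records
        assert "bounds" in skipped["mrnaA"]

    def test_nonzero_first_phase_rejected(self, toy_genome_writer):
        cds = _make_cds(99)
        contig = "T" * 10 + cds + "T" * 10
        gff = _single_exon_gff(11, 10 + len(cds)).replace("\t0\tID=cdsA", "\t2\tID=cdsA")
        fasta, gpath = toy_genome_writer(contig, gff)
        _, records, skipped = load_genome(fasta, gpath)
        assert not records and "phase" in skipped["mrnaA"]


def _record(gene_id: str, cds: str, *, tid: str | None = None, pseudo=False) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id, transcript_id=tid or f"{gene_id}.t1", contig="chr1",
        strand="+", exons=[(0, len(cds))], cds=cds, pseudo=pseudo,
    )


class TestFilterCDS:
    def test_each_rule_rejects_one_violator(self):
        clean = "ATG" + "GCT" * 100 + "TAA"  # 306 bp
        violators = [
            _record("g1", "ATG" + "GCT" * 100 + "TA"),           # not multiple of 3
            _record("g2", "TTG" + "GCT" * 100 + "TAA"),          # bad start
            _record("g3", "ATG" + "GCT" * 100 + "GCA"),          # bad stop
            _record("g4", "ATG" + "GCT" * 50 + "TAA" + "GCT" * 50 + "TAA"),  # internal stop
            _record("g5", "ATG" + "GCT" * 30 + "TAA"),           # 96 bp, too short
            _record("g6", "ATG" + "GCN" + "GCT" * 99 + "TAA"),   # ambiguity
            _record("g7", clean),
        ]
        passed, tally = filter_cds(violators)
        assert [r.gene_id for r in passed] == ["g7"]
        assert sum(tally.values()) == 6
        assert passed[0].status == "pass"
        assert violators[0].status == "fail:not_multiple_of_three"

    def test_length_exactly_300_rejected(self):
        rec = _record("g1", "ATG" + "GCT" * 98 + "TAA")
        assert len(rec.cds) == 300
        passed, tally = filter_cds([rec])
        assert not passed and tally["too_short"] == 1

    def test_internal_stop_rejected(self):
        rec = _record("g1", "ATGTAA" + "AAA" * 99 + "TAA")
        passed, tally = filter_cds([rec])
        assert not passed and tally["internal_stop"] == 1

    def test_pseudogene_rejected(self):
        rec = _record("g1", "ATG" + "GCT" * 100 + "TAA", pseudo=True)
        passed, tally = filter_cds([rec])
        assert not passed and tally["pseudogene"] == 1

    def test_longest_transcript_kept_with_id_tiebreak(self):
        long = _record("g1", "ATG" + "GCT" * 120 + "TAA", tid="g1.t2")
        short = _record("g1", "ATG" + "GCT" * 110 + "TAA", tid="g1.t1")
        tie_b = _record("g2", "ATG" + "GCA" * 120 + "TAA", tid="g2.tB")
        tie_a = _record("g2", "ATG" + "GCC" * 120 + "TAA", tid="g2.tA")
        passed, tally = filter_cds([short, long, tie_b, tie_a])
        kept = {r.transcript_id for r in passed}
        assert kept == {"g1.t2", "g2.tA"}
        assert tally["not_longest_isoform"] == 2

    def test_empty_input(self):
        passed, tally = filter_cds([])
        assert passed == [] and sum(tally.values()) == 0


class TestFlanks:
    def _contigs(self, length=2000):
        return ContigSet({"chr1": "ACGT" * (length // 4)})

    def test_full_clearance_gives_200_each(self):
        rec = _record("g", "ATG")
        rec.exons = [(900, 1000)]
        f5, f3 = extract_flanks(rec, self._contigs(), [])
        assert len(f5) == 200 and len(f3) == 200

    def test_contig_start_truncates(self):
        rec = _record("g", "ATG")
        rec.exons = [(50, 150)]
        f5, f3 = extract_flanks(rec, self._contigs(), [])
        assert len(f5) == 50

    def test_neighbor_truncates(self):
        rec = _record("g", "ATG")
        rec.exons = [(500, 600)]
        f5, f3 = extract_flanks(rec, self._contigs(), [(720, 800)])
        assert len(f3) == 120 and len(f5) == 200

    def test_abutting_neighbor_gives_empty_flank(self):
        rec = _record("g", "ATG")
        rec.exons = [(500, 600)]
        f5, f3 = extract_flanks(rec, self._contigs(), [(600, 700)])
        assert f3 == ""

    def test_minus_strand_orientation(self):
        contigs = ContigSet({"chr1": "A" * 500 + "GGGGG" + "A" * 495})
        rec = _record("g", "ATG")
        rec.strand = "-"
        rec.exons = [(505, 605)]
        f5, f3 = extract_flanks(rec, contigs, [], flank=5)
        # 5' flank of a minus-strand gene is downstream in contig coords
        assert f3 == reverse_complement("GGGGG")


class TestIntrons:
    def test_concatenation(self):
        rec = _record("g", "ATG")
        rec.introns = ["A" * 40, "C" * 60]
        assert concatenate_introns(rec) == "A" * 40 + "C" * 60

    def test_intronless_absent(self):
        assert concatenate_introns(_record("g", "ATG")) is None


def test_fasta_round_trip(tmp_path, small_genome):
    sub = dict(list(small_genome.sequences.items())[:30])
    path = tmp_path / "genes.fa"
    write_fasta(path, sub)
    assert read_fasta(path) == sub


def test_strand_symmetry_of_pipeline(tmp_path):
    """Mirroring every contig (revcomp + mirrored GFF3) leaves the pass set
    and all CDS sequences unchanged."""
    genome = generate_genome(
        SyntheticSpec(seed=5, n_genes=30, genes_per_contig=10, trna_complement={})
    )
    paths = genome.write(tmp_path / "fwd")

    # build the mirrored genome
    lengths = {cid: len(seq) for cid, seq in genome.contigs.items()}
    mirrored = {cid: reverse_complement(seq) for cid, seq in genome.contigs.items()}
    out = tmp_path / "rev"
    out.mkdir()
    write_fasta(out / "genome.fa", mirrored)
    lines = []
    for line in paths["gff3"].read_text().splitlines():
        if line.startswith("#"):
            lines.append(line)
            continue
        f = line.split("\t")
        length = lengths[f[0]]
        start, end = int(f[3]), int(f[4])
        f[3], f[4] = str(length - end + 1), str(length - start + 1)
        f[6] = "-" if f[6] == "+" else "+"
        lines.append("\t".join(f))
    (out / "genes.gff3").write_text("\n".join(lines) + "\n")

    _, fwd_records, _ = load_genome(paths["fasta"], paths["gff3"])
    _, rev_records, _ = load_genome(out / "genome.fa", out / "genes.gff3")
    fwd_pass, _ = filter_cds(fwd_records)
    rev_pass, _ = filter_cds(rev_records)
    assert {r.gene_id: r.cds for r in fwd_pass} == {r.gene_id: r.cds for r in rev_pass}
    assert {r.gene_id: r.introns[0] if r.introns else None for r in fwd_pass} == {
        r.gene_id: r.introns[0] if r.introns else None for r in rev_pass
    }
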