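"""Shared fixtures: tiny hand-built genomes and cached simulations."""

from __future__ import annotations

import textwrap

import pytest

from cubkit.synthetic_data import SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 200-gene default-condition synthetic genome (session-cached)."""
    return generate_genome(SyntheticSpec(seed=42, n_genes=200))


def write_toy_genome(tmp_path, contig_seq: str, gff_body: str):
    """Write a single-contig FASTA and a GFF3 body to disk."""
    fasta = tmp_path / "toy.fa"
    fasta.write_text(f">chr1\n{contig_seq}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text("##gff-version 3\n" + textwrap.dedent(gff_body))
    return fasta, gff


@pytest.fixture
def toy_genome_writer(tmp_path):
    def _write(contig_seq: str, gff_body: str):
        return write_toy_genome(tmp_path, contig_seq, gff_body)

    return _write
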