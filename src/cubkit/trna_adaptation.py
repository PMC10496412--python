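"""tRNA gene complements and codon-anticodon matching.

Parses tRNAscan-SE 2.x tabular output, tallies anticodon copy numbers,
calls the major tRNA gene per amino acid (the most abundant one), and
classifies optimal-codon ↔ anticodon pairings as Watson–Crick, G:U
wobble, or inosine-mediated.

Anticodons are stored 5'->3' in the DNA alphabet exactly as tRNAscan-SE
emits them; the wobble position (position 34) is therefore the *first*
character of the anticodon string, and Watson–Crick matching reverses
and complements.  An adenosine at position 34 is assumed deaminated to
inosine (I34), which reads codons ending in U, C or A: the U case is
also a plain A:U pair and is reported as Watson–Crick, the C and A cases
as inosine, keeping the classes mutually exclusive.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genetic_code import (
    COMPLEMENT,
    THREE_TO_ONE,
    reverse_complement,
)
from .stratification import OptimalCodonSet

__all__ = [
    "TRNAGene",
    "parse_trnascan",
    "copy_numbers",
    "major_trna",
    "classify_match",
    "optimal_vs_major",
    "MATCH_CLASSES",
]

MATCH_CLASSES = ("watson_crick", "gu_wobble", "inosine", "none")

_VALID = frozenset("ACGT")


@dataclass
class TRNAGene:
    """One tRNA gene prediction."""

    contig: str
    begin: int
    end: int
    isotype: str  # as printed: 'Gly', 'SeC', 'Pseudo', 'Und', ...
    anticodon: str  # 5'->3', DNA alphabet
    score: float
    pseudo: bool = False

    @property
    def is_selenocysteine(self) -> bool:
        return self.isotype.startswith("SeC")

    @property
    def amino_acid(self) -> str | None:
        """One-letter amino acid for standard isotypes, else None."""
        return THREE_TO_ONE.get(self.isotype)


def parse_trnascan(path: str | Path) -> list[TRNAGene]:
    """Read tRNAscan-SE 2.x tabular output.

    Header lines (everything up to and including the dashed rule) are
    skipped; malformed data rows are skipped as well.  Pseudogene calls
    are flagged via the isotype column or a 'pseudo' note.
    """
    genes: list[TRNAGene] = []
    lines = Path(path).read_text().splitlines()
    in_body = False
    for line in lines:
        if not in_body:
            if line.lstrip().startswith("---"):
                in_body = True
            continue
        parts = line.split()
        if len(parts) < 9:
            continue
        try:
            gene = TRNAGene(
                contig=parts[0],
                begin=int(parts[2]),
                end=int(parts[3]),
                isotype=parts[4],
                anticodon=parts[5].upper().replace("U", "T"),
                score=float(parts[8]),
                pseudo=(parts[4] == "Pseudo"
                        or any("pseudo" in p.lower() for p in parts[9:])),
            )
        except (ValueError, IndexError):
            continue
        genes.append(gene)
    return genes


def copy_numbers(
    genes: list[TRNAGene], *, include_pseudo: bool = False
) -> dict[str, Counter]:
    """Per-amino-acid anticodon copy numbers (one-letter aa keys).

    Pseudogenes (unless ``include_pseudo``), undetermined isotypes and
    selenocysteine genes are excluded from the 20-amino-acid tallies;
    SeC genes are retained on the gene list and can be inspected via
    :attr:`TRNAGene.is_selenocysteine`.
    """
    tallies: dict[str, Counter] = {}
    for g in genes:
        if g.pseudo and not include_pseudo:
            continue
        if g.is_selenocysteine:
            continue
        aa = g.amino_acid
        if aa is None or not _VALID.issuperset(g.anticodon) or len(g.anticodon) != 3:
            continue
        tallies.setdefault(aa, Counter())[g.anticodon] += 1
    return tallies


def major_trna(tallies: Mapping[str, Counter]) -> dict[str, tuple[str, ...]]:
    """Most abundant anticodon(s) per amino acid; ties are co-major."""
    majors: dict[str, tuple[str, ...]] = {}
    for aa, counter in tallies.items():
        if not counter:
            continue
        mx = max(counter.values())
        majors[aa] = tuple(sorted(a for a, n in counter.items() if n == mx))
    return majors


def classify_match(codon: str, anticodon: str) -> str:
    """Pairing class of a codon against a 5'->3' anticodon.

    * ``watson_crick`` — codon equals the reverse complement of the
      anticodon;
    * ``gu_wobble`` — codon positions 1-2 Watson–Crick, G at the
      anticodon wobble position (34) reading a U-ending codon;
    * ``inosine`` — codon positions 1-2 Watson–Crick, A at position 34
      (deaminated to inosine) reading a C- or A-ending codon;
    * ``none`` otherwise.
    """
    codon, anticodon = codon.upper(), anticodon.upper()
    for trip in (codon, anticodon):
        if len(trip) != 3 or not _VALID.issuperset(trip):
            raise ValueError(f"invalid triplet {trip!r}")
    if codon == reverse_complement(anticodon):
        return "watson_crick"
    if codon[0] != COMPLEMENT[anticodon[2]] or codon[1] != COMPLEMENT[anticodon[1]]:
        return "none"
    wobble = anticodon[0]
    if wobble == "G" and codon[2] == "T":
        return "gu_wobble"
    if wobble == "A" and codon[2] in ("C", "A"):
        return "inosine"
    return "none"


def optimal_vs_major(
    optimal: OptimalCodonSet,
    majors: Mapping[str, tuple[str, ...]],
    tallies: Mapping[str, Counter] | None = None,
) -> pd.DataFrame:
    """Match every optimal codon against its amino acid's major tRNA(s).

    The best class across co-major anticodons is reported with the
    precedence watson_crick > gu_wobble > inosine > none; optimal codons
    whose amino acid has no tRNA gene at all are ``none`` with an empty
    anticodon.
    """
    precedence = {c: i for i, c in enumerate(MATCH_CLASSES)}
    rows = []
    for codon, opt in sorted(
        optimal.codons.items(), key=lambda kv: (kv[1].amino_acid, kv[0])
    ):
        anticodons = majors.get(opt.amino_acid, ())
        best_class, best_anticodon = "none", ""
        for anti in anticodons:
            cls = classify_match(codon, anti)
            if precedence[cls] < precedence[best_class]:
                best_class, best_anticodon = cls, anti
        if not anticodons:
            best_anticodon = ""
        copy_n = 0
        if tallies is not None and best_anticodon:
            copy_n = tallies[opt.amino_acid][best_anticodon]
        rows.append({
            "amino_acid": opt.amino_acid,
            "optimal_codon": codon,
            "major_anticodon": best_anticodon or ",".join(anticodons),
            "copy_number": copy_n,
            "match_class": best_class,
        })
    return pd.DataFrame(rows, columns=[
        "amino_acid", "optimal_codon", "major_anticodon",
        "copy_number", "match_class",
    ])
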