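"""Standard genetic code tables used throughout the package.

Everything is in the DNA alphabet (T, not U); codons are written 5'->3'.
The degeneracy bookkeeping here is what the codon-usage metrics are built
on: 61 sense codons, of which 59 are synonymous (the single-codon amino
acids Met/ATG and Trp/TGG carry no usage information), grouped into 18
degenerate families — nine 2-fold, one 3-fold (Ile), five 4-fold and
three 6-fold (Leu, Ser, Arg).
"""

from __future__ import annotations

from itertools import product

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASES = ("T", "C", "A", "G")

#: codon -> one-letter amino acid, '*' for stop (standard code, table 1)
CODON_TABLE: dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
for _i, (_b1, _b2, _b3) in enumerate(product(BASES, BASES, BASES)):
    CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[_i]

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(c for c in CODON_TABLE if CODON_TABLE[c] != "*")

#: amino acid -> tuple of codons, degenerate families only (Met/Trp excluded)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    if _aa == "*":
        continue
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
for _aa in ("M", "W"):
    del SYNONYMOUS_FAMILIES[_aa]

#: the 59 codons that carry synonymous-usage information
SYNONYMOUS_CODONS = tuple(
    c for fam in SYNONYMOUS_FAMILIES.values() for c in fam
)

DEGENERACY = {aa: len(fam) for aa, fam in SYNONYMOUS_FAMILIES.items()}

#: the nine 2-fold degenerate amino acids used for selection-strength S
TWO_FOLD_AA = tuple(aa for aa, d in DEGENERACY.items() if d == 2)

AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
THREE_TO_ONE = {v: k for k, v in AA_THREE_LETTER.items()}


def complement(base: str) -> str:
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN only)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon; '*' for stop."""
    return CODON_TABLE[codon]


def is_gc(base: str) -> bool:
    return base in ("G", "C")


def anticodon_to_codon(anticodon: str) -> str:
    """The Watson-Crick codon read by a 5'->3' anticodon."""
    return reverse_complement(anticodon)


def amino_acid_of_anticodon(anticodon: str) -> str:
    """Amino acid decoded by an anticodon under Watson-Crick pairing."""
    return CODON_TABLE[reverse_complement(anticodon)]
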