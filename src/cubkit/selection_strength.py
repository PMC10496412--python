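"""Translational selection strength from 2-fold degenerate amino acids.

For each of the nine 2-fold degenerate amino acids (Phe, Tyr, His, Gln,
Asn, Lys, Asp, Glu, Cys) the optimal-codon frequency is contrasted
between the high- and low-bias gene categories as a 2x2 odds ratio

    OR = (f1H / f2H) * (f2L / f1L)

with 1 = optimal, 2 = suboptimal codon, H/L = high/low category.
S = ln(OR) is the per-amino-acid selection strength, and the
genome-level statistic Ŝ is the mean of S weighted by each amino acid's
codon total in the high-bias category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import pandas as pd

from .codon_metrics import CodonCountTable, rscu
from .genetic_code import SYNONYMOUS_FAMILIES, TWO_FOLD_AA
from .stratification import OptimalCodonSet

__all__ = [
    "TwoFoldTally",
    "SelectionStrengthResult",
    "two_fold_tallies",
    "odds_ratio",
    "s_hat",
    "selection_strength",
]


@dataclass
class TwoFoldTally:
    """Optimal/suboptimal codon counts of one 2-fold amino acid."""

    amino_acid: str
    optimal_codon: str
    suboptimal_codon: str
    n1h: int  # optimal, high category
    n2h: int  # suboptimal, high category
    n1l: int  # optimal, low category
    n2l: int  # suboptimal, low category
    optimal_by_fallback: bool = False  # no called optimal codon; used RSCU_high

    @property
    def frequencies(self) -> tuple[float, float, float, float]:
        """(f1H, f2H, f1L, f2L); nan when a category pool is empty."""
        nh, nl = self.n1h + self.n2h, self.n1l + self.n2l
        f = lambda n, tot: n / tot if tot else math.nan
        return (f(self.n1h, nh), f(self.n2h, nh), f(self.n1l, nl), f(self.n2l, nl))


@dataclass
class SelectionStrengthResult:
    """Per-amino-acid odds ratios/S and the weighted genome statistic Ŝ."""

    per_amino_acid: pd.DataFrame  # amino_acid, codons, counts, OR, S, weight
    s_hat: float
    dropped: list[str]  # amino acids without a defined OR

    def to_frame(self) -> pd.DataFrame:
        return self.per_amino_acid


def two_fold_tallies(
    high: CodonCountTable,
    low: CodonCountTable,
    optimal: OptimalCodonSet | None = None,
) -> tuple[list[TwoFoldTally], list[str]]:
    """Per-2-fold-amino-acid optimal/suboptimal counts in both pools.

    The optimal codon is the one called in ``optimal``; an amino acid
    with no called optimal codon falls back to the codon with the higher
    pooled RSCU in the high category (flagged).  Amino acids absent from
    either pool are dropped (returned in the log list).
    """
    rscu_high = rscu(high)
    tallies: list[TwoFoldTally] = []
    dropped: list[str] = []
    for aa in TWO_FOLD_AA:
        c1, c2 = SYNONYMOUS_FAMILIES[aa]
        if high.family_count(aa) == 0 or low.family_count(aa) == 0:
            dropped.append(aa)
            continue
        called = optimal.for_amino_acid(aa) if optimal is not None else []
        fallback = not called
        if called:
            opt = called[0]
        elif rscu_high[c1] >= rscu_high[c2]:
            opt = c1
        else:
            opt = c2
        sub = c2 if opt == c1 else c1
        tallies.append(
            TwoFoldTally(
                amino_acid=aa,
                optimal_codon=opt,
                suboptimal_codon=sub,
                n1h=high.counts[opt], n2h=high.counts[sub],
                n1l=low.counts[opt], n2l=low.counts[sub],
                optimal_by_fallback=fallback,
            )
        )
    return tallies, dropped


def odds_ratio(
    tally: TwoFoldTally,
    *,
    continuity: bool = False,
    literal_eq1: bool = False,
) -> tuple[float, float]:
    """(OR, S) for one tally; S = ln(OR).

    A zero cell makes the ratio undefined (nan) unless ``continuity``
    applies the Haldane–Anscombe 0.5 pseudo-count to all four cells.
    ``literal_eq1`` evaluates the printed form f1H/f2H * f2L/f1H (with
    the repeated f1H denominator) for audit purposes; the default is the
    standard 2x2 odds ratio.
    """
    n1h, n2h, n1l, n2l = tally.n1h, tally.n2h, tally.n1l, tally.n2l
    if continuity and 0 in (n1h, n2h, n1l, n2l):
        n1h, n2h, n1l, n2l = (n + 0.5 for n in (n1h, n2h, n1l, n2l))
    nh, nl = n1h + n2h, n1l + n2l
    if nh == 0 or nl == 0:
        return math.nan, math.nan
    f1h, f2h, f1l, f2l = n1h / nh, n2h / nh, n1l / nl, n2l / nl
    denom = f1h if literal_eq1 else f1l
    if f2h == 0 or denom == 0 or f1h == 0 or f2l == 0:
        return math.nan, math.nan
    or_ = (f1h / f2h) * (f2l / denom)
    return or_, math.log(or_)


def s_hat(s_values: Sequence[float], weights: Sequence[float]) -> float:
    """Codon-count-weighted mean of S over amino acids with defined S."""
    pairs = [(s, w) for s, w in zip(s_values, weights) if not math.isnan(s)]
    if not pairs:
        raise ValueError("no defined S values to average")
    wsum = sum(w for _, w in pairs)
    return sum(s * w for s, w in pairs) / wsum


def selection_strength(
    high: CodonCountTable,
    low: CodonCountTable,
    optimal: OptimalCodonSet | None = None,
    *,
    continuity: bool = False,
) -> SelectionStrengthResult:
    """Full selection-strength analysis from pooled category counts.

    Weights for Ŝ are each amino acid's total codon count in the
    high-bias category (n1H + n2H).
    """
    tallies, dropped = two_fold_tallies(high, low, optimal)
    rows = []
    for t in tallies:
        or_, s = odds_ratio(t, continuity=continuity)
        if math.isnan(s):
            dropped.append(t.amino_acid)
        rows.append({
            "amino_acid": t.amino_acid,
            "optimal_codon": t.optimal_codon,
            "suboptimal_codon": t.suboptimal_codon,
            "n1H": t.n1h, "n2H": t.n2h, "n1L": t.n1l, "n2L": t.n2l,
            "odds_ratio": or_, "S": s,
            "weight": t.n1h + t.n2h,
            "optimal_by_fallback": t.optimal_by_fallback,
        })
    df = pd.DataFrame(rows, columns=[
        "amino_acid", "optimal_codon", "suboptimal_codon",
        "n1H", "n2H", "n1L", "n2L", "odds_ratio", "S", "weight",
        "optimal_by_fallback",
    ])
    shat = s_hat(df["S"].tolist(), df["weight"].tolist()) if len(df) else math.nan
    return SelectionStrengthResult(per_amino_acid=df, s_hat=shat, dropped=dropped)
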