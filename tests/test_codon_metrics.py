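"""Per-gene metric correctness: counts, RSCU, GC family, Nc, CAI, CBI, Fop."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table
from hypothesis import given, settings, strategies as st

from cubkit.codon_metrics import (
    CodonCountTable,
    cai,
    cai_weights,
    cbi,
    count_codons,
    effective_number_of_codons,
    fop,
    gc_family,
    metrics_table,
    rscu,
)
from cubkit.genetic_code import SYNONYMOUS_CODONS, SYNONYMOUS_FAMILIES

# ---------------------------------------------------------------------------
# independent Nc oracle: family structure from Biopython's codon table,
# homozygosity by direct summation


def _biopython_families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        if set(codon) <= set("ACGT"):
            fams.setdefault(aa, []).append(codon)
    return {aa: sorted(f) for aa, f in fams.items() if len(f) > 1}


def brute_force_nc(counts: dict[str, int]) -> float:
    by_class: dict[int, list[float]] = {}
    for aa, fam in _biopython_families().items():
        n = sum(counts.get(c, 0) for c in fam)
        if n <= 1:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in fam) - 1) / (n - 1)
        if f <= 0:
            continue
        by_class.setdefault(len(fam), []).append(f)
    means = {d: sum(v) / len(v) for d, v in by_class.items()}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if any(d not in means for d in (2, 3, 4, 6)):
        return math.nan
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(nc, 61.0)


def _table(counts: dict[str, int]) -> CodonCountTable:
    return CodonCountTable(counts=Counter(counts))


# ---------------------------------------------------------------------------


class TestCountCodons:
    def test_simple_cds(self):
        t = count_codons("ATGTTTTAA")
        assert t.counts == {"ATG": 1, "TTT": 1}
        assert t.stops == {"TAA": 1}
        assert t.total_sense == 2

    def test_empty(self):
        t = count_codons("")
        assert t.total_sense == 0 and not t.stops

    def test_ambiguous_codon_skipped(self):
        t = count_codons("ATGTTNTAA")
        assert t.counts == {"ATG": 1}
        assert t.skipped == 1

    def test_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError):
            count_codons("ATGT")


class TestRSCU:
    def test_two_fold_skew(self):
        vals = rscu(_table({"TTT": 2, "TTC": 1}))
        assert vals["TTT"] == pytest.approx(4 / 3)
        assert vals["TTC"] == pytest.approx(2 / 3)

    def test_uniform_four_fold(self):
        vals = rscu(_table({c: 5 for c in ("GGT", "GGC", "GGA", "GGG")}))
        assert all(vals[c] == pytest.approx(1.0) for c in ("GGT", "GGC", "GGA", "GGG"))

    def test_exclusive_codon(self):
        vals = rscu(_table({"GCA": 4}))
        assert vals["GCA"] == pytest.approx(4.0)

    def test_absent_family_is_missing_not_zero(self):
        vals = rscu(_table({"TTT": 1}))
        assert math.isnan(vals["GGC"])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 30), min_size=59, max_size=59))
    def test_family_sums_equal_degeneracy(self, raw):
        counts = dict(zip(SYNONYMOUS_CODONS, raw))
        vals = rscu(_table(counts))
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if sum(counts[c] for c in fam):
                assert sum(vals[c] for c in fam) == pytest.approx(len(fam))


class TestGCFamily:
    def test_all_gcg(self):
        g = gc_family(count_codons("GCG" * 20))
        assert g["GC3"] == 1.0 and g["GC3s"] == 1.0

    def test_met_trp_only_has_no_silent_sites(self):
        g = gc_family(count_codons("ATGTGG" * 5))
        assert math.isnan(g["GC3s"])
        # A3..C3 default covers all sense codons, so they stay defined
        assert g["G3"] == 1.0

    def test_equal_glycine_thirds(self):
        g = gc_family(count_codons("GGA" * 3 + "GGT" * 3 + "GGC" * 3 + "GGG" * 3))
        assert g["A3"] == g["T3"] == g["G3"] == g["C3"] == 0.25

    def test_gc12_is_mean_of_gc1_gc2(self):
        g = gc_family(count_codons("ATGGCGTTTCACTAA"[:-3]))
        assert g["GC12"] == pytest.approx((g["GC1"] + g["GC2"]) / 2)


class TestNc:
    def test_uniform_usage_gives_61(self):
        cds = "ATG" + "".join(c * 10 for c in SYNONYMOUS_CODONS) + "TAA"
        assert effective_number_of_codons(count_codons(cds)) == 61.0

    def test_one_codon_per_amino_acid_gives_20(self):
        cds = "ATG" + "".join(
            fam[0] * 30 for fam in SYNONYMOUS_FAMILIES.values()
        ) + "TGG" * 30 + "TAA"
        assert effective_number_of_codons(count_codons(cds)) == pytest.approx(20.0)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            counts = {
                c: int(k)
                for c, k in zip(SYNONYMOUS_CODONS, rng.poisson(5, size=59))
            }
            ours = effective_number_of_codons(_table(counts))
            ref = brute_force_nc(counts)
            if math.isnan(ref):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-9)
                checked += 1
        assert checked > 150  # the comparison actually exercised defined Nc

    def test_invariant_to_synonymous_relabeling(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            counts = {
                c: int(k)
                for c, k in zip(SYNONYMOUS_CODONS, rng.poisson(4, size=59))
            }
            permuted: dict[str, int] = {}
            for fam in SYNONYMOUS_FAMILIES.values():
                vals = [counts[c] for c in fam]
                order = rng.permutation(len(fam))
                for c, i in zip(fam, order):
                    permuted[c] = vals[i]
            a = effective_number_of_codons(_table(counts))
            b = effective_number_of_codons(_table(permuted))
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_skew_weakly_decreases_nc(self):
        base = {c: 6 for c in SYNONYMOUS_CODONS}
        previous = effective_number_of_codons(_table(base))
        for shift in (2, 4, 6):  # move Phe usage 6/6 -> 8/4 -> 10/2 -> 12/0
            skewed = dict(base)
            skewed["TTT"], skewed["TTC"] = 6 + shift, 6 - shift
            current = effective_number_of_codons(_table(skewed))
            assert current <= previous + 1e-12
            previous = current


class TestCAI:
    def test_geometric_mean_sqrt(self):
        weights = {c: 1.0 for c in SYNONYMOUS_CODONS}
        weights["TTT"] = 0.5
        t = _table({"TTT": 1, "TTC": 1})
        assert cai(t, weights) == pytest.approx(math.sqrt(0.5))

    def test_maximal_usage_gives_one(self):
        weights = {c: 1.0 for c in SYNONYMOUS_CODONS}
        assert cai(_table({"GGC": 10, "AAG": 5}), weights) == pytest.approx(1.0)

    def test_cube_root(self):
        weights = {c: 1.0 for c in SYNONYMOUS_CODONS}
        weights.update({"TTT": 1.0, "TTC": 0.5, "GGC": 0.25})
        t = _table({"TTT": 1, "TTC": 1, "GGC": 1})
        assert cai(t, weights) == pytest.approx(0.5)

    def test_weights_floor_for_unused_reference_codons(self):
        ref = _table({"TTT": 10})  # TTC unseen in reference
        w = cai_weights(ref)
        assert w["TTT"] == 1.0 and w["TTC"] == 0.01


class TestFopCBI:
    def test_fop_examples(self):
        optimal = {"TTC", "GGC"}
        assert fop(_table({"TTC": 3, "TTT": 1}), optimal) == 0.75
        assert fop(_table({"TTT": 4}), optimal) == 0.0
        assert fop(_table({"TTC": 2, "GGC": 2}), optimal) == 1.0

    def test_cbi_worked_example(self):
        # two 2-fold families, one optimal codon each: N_opt=3 of N_tot=4
        optimal = {"TTC", "TAC"}
        t = _table({"TTC": 2, "TTT": 0, "TAC": 1, "TAT": 1})
        assert cbi(t, optimal) == pytest.approx(0.5)  # N_ran = 2

    def test_cbi_random_expectation_is_zero(self):
        t = _table({"TTC": 5, "TTT": 5})
        assert cbi(t, {"TTC"}) == pytest.approx(0.0)

    def test_cbi_exclusive_optimal_is_one(self):
        t = _table({"TTC": 7, "GGC": 3})
        assert cbi(t, {"TTC", "GGC"}) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 15), min_size=59, max_size=59))
    def test_bounds_on_fuzzed_tables(self, raw):
        counts = dict(zip(SYNONYMOUS_CODONS, raw))
        t = _table(counts)
        optimal = {fam[0] for fam in SYNONYMOUS_FAMILIES.values()}
        f = fop(t, optimal)
        c = cbi(t, optimal)
        weights = {cod: 1.0 if cod in optimal else 0.5 for cod in SYNONYMOUS_CODONS}
        a = cai(t, weights)
        if not math.isnan(f):
            assert 0.0 <= f <= 1.0
        if not math.isnan(c):
            assert -1.0 - 1e-9 <= c <= 1.0 + 1e-9
        if not math.isnan(a):
            assert 0.0 < a <= 1.0


def test_metrics_table_columns_and_types(small_genome):
    sub = dict(list(small_genome.sequences.items())[:20])
    df = metrics_table(sub)
    assert list(df.columns)[:5] == ["gene_id", "length_codons", "GC", "GC1", "GC2"]
    assert len(df) == 20
    assert df["Nc"].between(20, 61).all()
    assert (df["A3"] + df["T3"] + df["G3"] + df["C3"]).round(9).eq(1.0).all()
    assert df["stop_codon"].isin(["TAA", "TAG", "TGA"]).all()
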