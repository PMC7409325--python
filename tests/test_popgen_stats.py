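"""Diversity summaries, neutrality tests, and Fst against brute-force oracles."""

import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pytest

from mitopop.align_qc import AlignmentMatrix
from mitopop.popgen_stats import (
    call_variants,
    ewens_k_tail_probability,
    fus_Fs,
    hudson_fst,
    summarize_diversity,
    tajima_constants,
    tajimas_D,
)
from mitopop.simulate import (
    SimulationConfig,
    simulate_haplotypes,
    variants_to_alignment,
)


def aln_from(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return AlignmentMatrix.from_strings(ids, rows)


def random_alignment(seed, n=8, L=40):
    rng = random.Random(seed)
    base = [rng.choice("ACGT") for _ in range(L)]
    rows = []
    for _ in range(n):
        row = list(base)
        for c in range(L):
            r = rng.random()
            if r < 0.08:
                row[c] = rng.choice("ACGT")
            elif r < 0.12:
                row[c] = "N"
            elif r < 0.14:
                row[c] = "-"
        rows.append("".join(row))
    return aln_from(rows)


def brute_force_summary(aln):
    """Exhaustive pair/column enumeration — the oracle for every Table-1 stat."""
    rows = [aln.row_string(i) for i in range(aln.n_samples)]
    n, L = len(rows), len(rows[0])
    bases = set("ACGT")
    # polymorphic columns and transitions/transversions per allele pair
    S = ts = tv = 0
    per_col_pi = []
    for c in range(L):
        obs = [r[c] for r in rows if r[c] in bases]
        alleles = sorted(set(obs))
        if len(alleles) >= 2:
            S += 1
            for a, b in itertools.combinations(alleles, 2):
                if {a, b} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
        if len(obs) >= 2:
            diff = sum(
                a != b for a, b in itertools.combinations(obs, 2)
            )
            per_col_pi.append(diff / (len(obs) * (len(obs) - 1) / 2))
    # pairwise differences over all sample pairs
    diffs = [
        sum(
            1
            for c in range(L)
            if rows[i][c] in bases and rows[j][c] in bases and rows[i][c] != rows[j][c]
        )
        for i, j in itertools.combinations(range(n), 2)
    ]
    k = sum(diffs) / len(diffs)
    # haplotypes under complete deletion
    keep = [
        c for c in range(L) if all(r[c] in bases for r in rows)
    ]
    haps = {"".join(r[c] for c in keep) for r in rows}
    counts = {}
    for r in rows:
        h = "".join(r[c] for c in keep)
        counts[h] = counts.get(h, 0) + 1
    p2 = sum((v / n) ** 2 for v in counts.values())
    hd = n * (1 - p2) / (n - 1)
    return {
        "S": S,
        "ts": ts,
        "tv": tv,
        "k": k,
        "pi": sum(per_col_pi) / len(per_col_pi),
        "h": len(haps),
        "Hd": hd,
    }


class TestCallVariants:
    def test_column_with_single_base_plus_n_not_polymorphic(self):
        vt = call_variants(aln_from(["A", "A", "N"]))
        assert vt.n_sites == 0

    def test_transition_classification(self):
        vt = call_variants(aln_from(["A", "G", "A"]))
        assert vt.pair_classification(0) == ["transition"]

    def test_triallelic_site_classifies_each_pair(self):
        vt = call_variants(aln_from(["A", "G", "T", "A"]))
        assert sorted(vt.pair_classification(0)) == [
            "transition",
            "transversion",
            "transversion",
        ]

    def test_allele_counts_plus_missing_equals_sample_count(self):
        aln = random_alignment(1)
        vt = call_variants(aln)
        for s in range(vt.n_sites):
            assert sum(vt.allele_counts(s)) + vt.missing_count(s) == aln.n_samples


class TestSummaries:
    def test_identical_sequences(self):
        s = summarize_diversity(aln_from(["ACGT" * 5] * 6))
        assert (s.n_haplotypes, s.gene_diversity, s.mean_pairwise_differences) == (1, 0.0, 0.0)
        assert s.nucleotide_diversity == 0.0

    def test_two_sequences_three_differences(self):
        a = "A" * 100
        b = "A" * 97 + "TTT"
        s = summarize_diversity(aln_from([a, b]))
        assert s.mean_pairwise_differences == 3.0
        assert s.nucleotide_diversity == pytest.approx(0.03)
        assert s.gene_diversity == 1.0

    def test_hand_computed_gene_diversity(self):
        # haplotype counts (4,2,1,1) over 8 sequences: Hd = (8/7)(1 - 22/64)
        rows = ["AAAA"] * 4 + ["AAAT"] * 2 + ["AATT"],
        rows = ["AAAA"] * 4 + ["AAAT"] * 2 + ["AATT"] + ["ATTT"]
        s = summarize_diversity(aln_from(rows))
        assert s.n_haplotypes == 4
        assert s.gene_diversity == pytest.approx((8 / 7) * (1 - 22 / 64))
        assert s.gene_diversity == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle_equivalence(self, seed):
        aln = random_alignment(seed)
        s = summarize_diversity(aln)
        oracle = brute_force_summary(aln)
        assert s.n_polymorphic_sites == oracle["S"]
        assert s.transitions == oracle["ts"]
        assert s.transversions == oracle["tv"]
        assert s.n_haplotypes == oracle["h"]
        assert s.gene_diversity == pytest.approx(oracle["Hd"])
        assert s.mean_pairwise_differences == pytest.approx(oracle["k"])
        assert s.nucleotide_diversity == pytest.approx(oracle["pi"])

    def test_k_equals_pi_times_length_without_missing_data(self):
        rng = random.Random(3)
        rows = [
            "".join(rng.choice("ACGT") for _ in range(50)) for _ in range(6)
        ]
        s = summarize_diversity(aln_from(rows))
        assert s.mean_pairwise_differences == pytest.approx(
            s.nucleotide_diversity * 50
        )

    def test_composition_sums_to_one(self):
        s = summarize_diversity(random_alignment(4))
        assert sum(s.base_composition.values()) == pytest.approx(1.0)


class TestTajima:
    def test_monomorphic_returns_none(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert tajimas_D(aln_from(["AAAA"] * 4)) is None

    def test_hand_computed_singleton_case(self):
        # n=4, S=1 singleton: k = 2*1*3/12 = 0.5; D from the 1989 constants
        aln = aln_from(["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAATA"])
        res = tajimas_D(aln)
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1, b2 = 5 / 9, 2 * 23 / (9 * 12)
        c1 = b1 - 1 / a1
        c2 = b2 - 6 / (4 * a1) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (0.5 - 1 / a1) / math.sqrt(e1)
        assert res.D == pytest.approx(expected)
        assert res.theta_w == pytest.approx(1 / a1)

    def test_constructed_alignment_with_zero_D(self):
        # n=4: S=11 with 3 doubletons + 8 singletons gives k = S/a1 exactly
        cols = []
        for _ in range(3):  # doubletons: split 2/2
            cols.append("TTAA")
        for i in range(8):  # singletons rotate the carrier
            col = ["A"] * 4
            col[i % 4] = "G"
            cols.append("".join(col))
        rows = ["".join(c[i] for c in cols) + "A" * 20 for i in range(4)]
        res = tajimas_D(aln_from(rows))
        assert res.k == pytest.approx(res.S / tajima_constants(4)["a1"])
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_simulation_p_matches_beta_p_roughly(self):
        haps = simulate_haplotypes(
            SimulationConfig(seed=77, n_samples=25, theta=6.0, rho_background=0.0)
        )
        aln = variants_to_alignment(haps, coding_only=False)
        res = tajimas_D(aln, seed=5, n_simulations=2000)
        assert 0.0 <= res.p_simulation <= 1.0
        assert abs(res.p_simulation - res.p_beta) < 0.35


class TestFuFs:
    def test_tail_matches_sympy_rising_factorial_expansion(self):
        sympy = pytest.importorskip("sympy")
        n, theta = 10, 1.0
        x = sympy.Symbol("x")
        poly = sympy.Poly(
            sympy.prod([x + i for i in range(n)]), x
        )  # coefficients are the unsigned Stirling numbers
        coeffs = poly.all_coeffs()[::-1]  # index k -> |s(n, k)|
        denom = Fraction(1)
        for i in range(n):
            denom *= Fraction(theta) + i
        for k_obs in range(2, n + 1):
            expected = sum(
                Fraction(int(coeffs[k])) * Fraction(theta) ** k
                for k in range(k_obs, n + 1)
            ) / denom
            assert ewens_k_tail_probability(n, theta, k_obs) == pytest.approx(
                float(expected)
            )

    def test_all_distinct_haplotypes_gives_strongly_negative_fs(self):
        # 5 distinct haplotypes but tiny pairwise diversity
        rows = ["AAAAA", "TAAAA", "ATAAA", "AATAA", "AAATA"]
        res = fus_Fs(aln_from(rows), seed=0, n_replicates=200)
        assert res.Fs < -3

    def test_no_diversity_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            fus_Fs(aln_from(["AAA"] * 5))

    def test_p_value_in_unit_interval(self):
        haps = simulate_haplotypes(
            SimulationConfig(seed=21, n_samples=20, theta=4.0, rho_background=0.0)
        )
        res = fus_Fs(variants_to_alignment(haps, coding_only=False), seed=1, n_replicates=300)
        assert 0.0 <= res.p <= 1.0


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        aln = aln_from(["AAAA"] * 3 + ["TTTT"] * 3)
        assert hudson_fst(aln, ["s0", "s1", "s2"], ["s3", "s4", "s5"]) == pytest.approx(1.0)

    def test_identical_groups_give_near_zero(self):
        # two groups with identical composition (10 of each haplotype):
        # Hw = 4 * 100/190, Hb = 4 * 200/400; Fst = 1 - Hw/Hb = -1/19, the
        # usual small-sample bias of the within-group estimator
        rows = (["AATT"] * 10 + ["TTAA"] * 10) * 2
        aln = aln_from(rows)
        ids = aln.sample_ids
        got = hudson_fst(aln, ids[:20], ids[20:])
        assert got == pytest.approx(-1 / 19)
        assert abs(got) < 0.06

    def test_no_between_diversity_returns_none(self):
        aln = aln_from(["AAAA"] * 6)
        assert hudson_fst(aln, aln.sample_ids[:3], aln.sample_ids[3:]) is None

    def test_small_groups_rejected(self):
        aln = aln_from(["AAAA"] * 4)
        with pytest.raises(ValueError, match="at least 2"):
            hudson_fst(aln, aln.sample_ids[:1], aln.sample_ids[1:])

    def test_panmictic_split_is_near_zero(self):
        haps = simulate_haplotypes(
            SimulationConfig(seed=30, n_samples=50, theta=60.0, rho_background=30.0)
        )
        aln = variants_to_alignment(haps, coding_only=False)
        ids = aln.sample_ids
        fst = hudson_fst(aln, ids[:25], ids[25:])
        assert abs(fst) < 0.03
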