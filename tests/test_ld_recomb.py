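"""LD statistics, block calling, Rm, and the two-locus intensity machinery."""

import itertools
import random

import numpy as np
import pytest

from mitopop.align_qc import AlignmentMatrix
from mitopop.ld_recomb import (
    LDPair,
    _canonical_config,
    _two_locus_config,
    compute_ld_pairs,
    gabriel_blocks,
    hudson_kaplan_rm,
    maf_filter,
    pairwise_ld,
    recombination_intensity,
)
from mitopop.popgen_stats import VariantTable, call_variants
from mitopop.simulate import (
    SimulationConfig,
    simulate_haplotypes,
    variants_to_alignment,
)


def table_from_counts(nAB, nAb, naB, nab):
    """Two-site VariantTable realizing the given haplotype counts."""
    g = (
        [[0, 0]] * nAB + [[0, 1]] * nAb + [[1, 0]] * naB + [[1, 1]] * nab
    )
    g = np.array(g, dtype=np.int8)
    n = g.shape[0]
    return VariantTable(
        [f"s{i}" for i in range(n)],
        np.array([10, 20]),
        [["A", "T"], ["C", "G"]],
        g,
    )


def ld_oracle(nAB, nAb, naB, nab):
    """Direct textbook formulas for D, D' and r2 (independent of the module)."""
    n = nAB + nAb + naB + nab
    pA = (nAB + nAb) / n
    pB = (nAB + naB) / n
    D = nAB / n - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, dprime, r2


class TestMafFilter:
    def make(self, genotypes, alleles=None):
        g = np.array(genotypes, dtype=np.int8)
        alleles = alleles or [["A", "T"]] * g.shape[1]
        return VariantTable(
            [f"s{i}" for i in range(g.shape[0])],
            np.arange(g.shape[1]),
            alleles,
            g,
        )

    def test_exactly_ten_percent_removed(self):
        vt = self.make([[1]] * 1 + [[0]] * 9)
        assert maf_filter(vt, 0.10).n_sites == 0

    def test_above_threshold_kept(self):
        vt = self.make([[1]] * 11 + [[0]] * 89)
        assert maf_filter(vt, 0.10).n_sites == 1

    def test_triallelic_reduced_to_top_two(self):
        g = [[0]] * 6 + [[1]] * 3 + [[2]] * 1
        vt = self.make(g, alleles=[["A", "G", "T"]])
        out = maf_filter(vt, 0.10)
        assert out.n_sites == 1
        assert out.alleles[0] == ["A", "G"]
        # third allele became missing; MAF = 3/9 = 0.333
        assert out.minor_allele_frequency(0) == pytest.approx(1 / 3)
        assert out.missing_count(0) == 1


class TestPairwiseLD:
    def test_hand_computed_eight_haplotype_case(self):
        p = pairwise_ld(table_from_counts(3, 1, 1, 3), 0, 1)
        assert p.D == pytest.approx(0.125)
        assert p.r2 == pytest.approx(0.25)
        assert p.D_prime == pytest.approx(0.5)
        assert p.n_informative == 8

    def test_identical_columns_in_perfect_ld(self):
        p = pairwise_ld(table_from_counts(5, 0, 0, 5), 0, 1)
        assert p.D_prime == pytest.approx(1.0)
        assert p.r2 == pytest.approx(1.0)

    def test_monomorphic_site_returns_none(self):
        assert pairwise_ld(table_from_counts(5, 0, 5, 0), 0, 1) is None

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_small_tables_match_oracle(self, seed):
        rng = random.Random(seed)
        checked = 0
        for counts in itertools.product(range(11), repeat=4):
            if sum(counts) > 10 or sum(counts) < 4:
                continue
            if rng.random() > 0.05:  # subsample the grid, still hundreds of cases
                continue
            nAB, nAb, naB, nab = counts
            if (nAB + nAb) in (0, sum(counts)) or (nAB + naB) in (0, sum(counts)):
                continue
            p = pairwise_ld(table_from_counts(*counts), 0, 1)
            D, dp, r2 = ld_oracle(*counts)
            assert p.D == pytest.approx(D)
            assert p.D_prime == pytest.approx(min(dp, 1.0))
            assert p.r2 == pytest.approx(min(r2, 1.0))
            checked += 1
        assert checked > 20

    def test_confidence_interval_brackets_the_estimate(self):
        for counts in [(6, 1, 2, 5), (4, 4, 4, 4), (9, 0, 0, 1), (3, 1, 1, 3)]:
            p = pairwise_ld(table_from_counts(*counts), 0, 1)
            assert p.ci_low <= p.D_prime + 0.002
            assert p.ci_high >= p.D_prime - 0.002
            assert 0.0 <= p.ci_low <= p.ci_high <= 1.0

    def test_independent_sites_have_low_mean_r2(self):
        haps = simulate_haplotypes(
            SimulationConfig(seed=8, n_samples=60, theta=40.0, rho_background=200.0)
        )
        vt = maf_filter(call_variants(variants_to_alignment(haps)), 0.10)
        pairs = [
            pairwise_ld(vt, i, j)
            for i in range(0, vt.n_sites - 10, 5)
            for j in (i + 10,)
        ]
        r2s = [p.r2 for p in pairs if p is not None]
        # distant sites at very high rho: E[r2] ~ 1/n plus sampling noise
        assert np.mean(r2s) < 0.15


class TestBlocks:
    def pair(self, i, j, lo, hi):
        return LDPair(i, j, 0.1, min(hi, 1.0), 0.5, lo, hi, 20)

    def test_all_strong_recombination_yields_no_blocks(self):
        pairs = [self.pair(i, j, 0.1, 0.5) for i in range(4) for j in range(i + 1, 4)]
        assert gabriel_blocks(pairs, 4) == []

    def test_two_sites_in_perfect_ld_form_a_block(self):
        blocks = gabriel_blocks([self.pair(0, 1, 0.9, 1.0)], 2)
        assert [(b.first_site, b.last_site) for b in blocks] == [(0, 1)]
        assert blocks[0].n_sites == 2

    def test_greedy_keeps_longest_non_overlapping(self):
        strong = [(0, 1), (1, 2), (0, 2), (3, 4)]
        pairs = [self.pair(i, j, 0.9, 1.0) for i, j in strong]
        pairs.append(self.pair(2, 3, 0.1, 0.5))
        blocks = gabriel_blocks(pairs, 5)
        assert [(b.first_site, b.last_site) for b in blocks] == [(0, 2), (3, 4)]

    def test_sample_order_invariance(self):
        haps = simulate_haplotypes(
            SimulationConfig(seed=13, n_samples=30, theta=25.0, rho_background=10.0)
        )
        aln = variants_to_alignment(haps)
        vt = maf_filter(call_variants(aln), 0.10)
        blocks1 = gabriel_blocks(compute_ld_pairs(vt), vt.n_sites)
        perm = list(range(aln.n_samples))
        random.Random(0).shuffle(perm)
        aln2 = AlignmentMatrix(
            [aln.sample_ids[i] for i in perm], aln.codes[perm], aln.column_map
        )
        vt2 = maf_filter(call_variants(aln2), 0.10)
        blocks2 = gabriel_blocks(compute_ld_pairs(vt2), vt2.n_sites)
        assert blocks1 == blocks2


def brute_force_rm(variants):
    """Minimum cuts covering all incompatible intervals, by exhaustive search."""
    bad = [
        (i, j)
        for i in range(variants.n_sites)
        for j in range(i + 1, variants.n_sites)
        if len(
            {
                (int(a), int(b))
                for a, b in zip(variants.genotypes[:, i], variants.genotypes[:, j])
                if a >= 0 and b >= 0
            }
        )
        == 4
    ]
    if not bad:
        return 0
    gaps = range(variants.n_sites - 1)
    for k in range(1, len(bad) + 1):
        for cuts in itertools.combinations(gaps, k):
            if all(any(l <= c < r for c in cuts) for l, r in bad):
                return k
    return len(bad)


class TestRm:
    def test_canonical_four_gamete_pair(self):
        vt = table_from_counts(1, 1, 1, 1)
        rm, intervals = hudson_kaplan_rm(vt)
        assert rm == 1 and intervals == [(0, 1)]

    @pytest.mark.parametrize("seed", range(5))
    def test_no_recombination_means_no_incompatibilities(self, seed):
        haps = simulate_haplotypes(
            SimulationConfig(seed=100 + seed, n_samples=20, theta=20.0, rho_background=0.0)
        )
        vt = call_variants(variants_to_alignment(haps))
        assert hudson_kaplan_rm(vt)[0] == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_interval_cover(self, seed):
        haps = simulate_haplotypes(
            SimulationConfig(seed=200 + seed, n_samples=20, theta=15.0, rho_background=8.0)
        )
        vt = call_variants(variants_to_alignment(haps))
        if vt.n_sites > 30:  # keep the brute force tractable
            vt = VariantTable(
                vt.sample_ids, vt.columns[:30], vt.alleles[:30], vt.genotypes[:, :30]
            )
        assert hudson_kaplan_rm(vt)[0] == brute_force_rm(vt)

    def test_bounded_by_realized_event_count(self):
        for seed in range(5):
            haps = simulate_haplotypes(
                SimulationConfig(seed=300 + seed, n_samples=25, theta=25.0, rho_background=10.0)
            )
            vt = call_variants(variants_to_alignment(haps, coding_only=False))
            assert hudson_kaplan_rm(vt)[0] <= len(haps.event_positions)

    def test_monotone_in_added_sites(self):
        haps = simulate_haplotypes(
            SimulationConfig(seed=400, n_samples=25, theta=30.0, rho_background=15.0)
        )
        vt = call_variants(variants_to_alignment(haps))
        half = VariantTable(
            vt.sample_ids,
            vt.columns[::2],
            vt.alleles[::2],
            vt.genotypes[:, ::2],
        )
        assert hudson_kaplan_rm(half)[0] <= hudson_kaplan_rm(vt)[0]


class TestTwoLocusTable:
    def test_canonical_config_invariant_under_symmetries(self):
        rng = random.Random(1)
        for _ in range(100):
            c = tuple(rng.randrange(8) for _ in range(4))
            base = _canonical_config(*c)
            swaps = [
                (c[2], c[3], c[0], c[1]),  # relabel locus A alleles
                (c[1], c[0], c[3], c[2]),  # relabel locus B alleles
                (c[0], c[2], c[1], c[3]),  # exchange loci
            ]
            for s in swaps:
                assert _canonical_config(*s) == base

    def test_replicate_configs_are_segregating(self):
        rng = random.Random(2)
        for _ in range(50):
            n11, n10, n01, n00 = _two_locus_config(10, 2.0, rng)
            n = n11 + n10 + n01 + n00
            assert n == 10
            assert 0 < n11 + n10 < n and 0 < n11 + n01 < n

    def test_perfect_ld_favours_zero_rho(self, small_two_locus_table):
        assert small_two_locus_table.best_rho((5, 0, 0, 5)) == 0.0

    def test_save_load_round_trip(self, small_two_locus_table, tmp_path):
        path = tmp_path / "table.json"
        small_two_locus_table.save(path)
        from mitopop.ld_recomb import TwoLocusTable

        back = TwoLocusTable.load(path)
        assert back.n == small_two_locus_table.n
        assert back.counts == small_two_locus_table.counts
        assert back.best_rho((5, 0, 0, 5)) == small_two_locus_table.best_rho(
            (5, 0, 0, 5)
        )


class TestIntensityProfile:
    def test_uniform_recombination_has_unit_median_intensity(self, small_two_locus_table):
        haps = simulate_haplotypes(
            SimulationConfig(seed=500, n_samples=30, theta=40.0, rho_background=15.0)
        )
        vt = maf_filter(call_variants(variants_to_alignment(haps)), 0.10)
        prof = recombination_intensity(vt, small_two_locus_table, seed=1)
        lams = [iv.intensity for iv in prof.intervals if iv.intensity is not None]
        assert np.median(lams) == pytest.approx(1.0)

    def test_rm_contributions_sum_to_total(self, small_two_locus_table):
        haps = simulate_haplotypes(
            SimulationConfig(seed=501, n_samples=30, theta=40.0, rho_background=15.0)
        )
        vt = maf_filter(call_variants(variants_to_alignment(haps)), 0.10)
        prof = recombination_intensity(vt, small_two_locus_table, seed=1)
        assert sum(iv.rm_contribution for iv in prof.intervals) == prof.rm_total
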