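"""PCA, ancestry factorization, NJ trees, and group-Fst structure."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from mitopop.io_formats import SampleMetadata
from mitopop.ld_recomb import maf_filter
from mitopop.njtree import neighbor_joining
from mitopop.popgen_stats import call_variants
from mitopop.structure import (
    GenotypeMatrix,
    encode_genotypes,
    group_fst_tree,
    nmf_ancestry,
    pairwise_snp_distance,
    pca,
    remove_outliers_and_rerun,
)
from mitopop.align_qc import AlignmentMatrix
from mitopop.simulate import (
    SimulationConfig,
    simulate_haplotypes,
    variants_to_alignment,
)


def unrooted_rf(newick_a: str, newick_b: str, names) -> int:
    """Robinson-Foulds distance between two trees compared as unrooted."""
    ns = dendropy.TaxonNamespace(names)
    trees = []
    for nwk in (newick_a, newick_b):
        t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns)
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.update_bipartitions()
        trees.append(t)
    return dendropy.calculate.treecompare.symmetric_difference(*trees)


def two_pop_gm(seed=11, n=30, migration=0.005, admixture=()):
    cfg = SimulationConfig(
        seed=seed,
        n_samples=n,
        n_populations=2,
        migration=migration,
        theta=60.0,
        rho_background=50.0,
        admixture=admixture,
    )
    haps = simulate_haplotypes(cfg)
    gm = encode_genotypes(maf_filter(call_variants(variants_to_alignment(haps)), 0.10))
    return gm, haps


class TestEncode:
    def aln(self, rows):
        return AlignmentMatrix.from_strings([f"s{i}" for i in range(len(rows))], rows)

    def test_minor_allele_is_lower_frequency(self):
        gm = encode_genotypes(maf_filter(call_variants(self.aln(["A"] * 7 + ["T"] * 3)), 0.1))
        assert gm.major_alleles == ["A"] and gm.minor_alleles == ["T"]
        assert gm.data[:, 0].sum() == 3

    def test_fifty_fifty_tie_makes_later_allele_minor(self):
        gm = encode_genotypes(maf_filter(call_variants(self.aln(["A", "T"] * 5)), 0.1))
        assert gm.minor_alleles == ["T"]

    def test_round_trip_through_vcf_preserves_encoding(self, tmp_path):
        from mitopop.io_formats import read_variants_vcf, write_variants_vcf

        haps = simulate_haplotypes(
            SimulationConfig(seed=3, n_samples=12, theta=20.0, rho_background=5.0)
        )
        vt = maf_filter(call_variants(variants_to_alignment(haps)), 0.10)
        write_variants_vcf(vt, tmp_path / "v.vcf")
        back = read_variants_vcf(tmp_path / "v.vcf")
        assert np.array_equal(
            encode_genotypes(vt).data, encode_genotypes(back).data
        )


class TestPca:
    def test_well_separated_populations_split_on_pc1(self):
        gm, _ = two_pop_gm(seed=501)
        pc1 = pca(gm, 10).coordinates[:, 0]
        n = 30
        errors = min(
            (pc1[:n] > 0).sum() + (pc1[n:] <= 0).sum(),
            (pc1[:n] <= 0).sum() + (pc1[n:] > 0).sum(),
        )
        assert errors == 0

    def test_duplicated_sample_gets_identical_coordinates(self):
        gm, _ = two_pop_gm(seed=502)
        dup = GenotypeMatrix(
            gm.sample_ids + ["dup"],
            np.vstack([gm.data, gm.data[:1]]),
            gm.columns,
            gm.minor_alleles,
            gm.major_alleles,
        )
        res = pca(dup, 5)
        assert np.allclose(res.coordinates[0], res.coordinates[-1], atol=1e-8)

    def test_coordinates_are_orthogonal_and_fractions_sum_to_one(self):
        gm, _ = two_pop_gm(seed=503)
        res = pca(gm, 10)
        gram = res.coordinates.T @ res.coordinates
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-6)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_too_few_samples_rejected(self):
        gm, _ = two_pop_gm(seed=504, n=4)
        with pytest.raises(ValueError, match="n_pcs"):
            pca(gm, 10)


class TestOutliers:
    def test_planted_outliers_flagged_and_removed(self):
        gm, _ = two_pop_gm(seed=505, n=25, migration=5.0)  # one loose cloud
        # three samples carrying the minor allele everywhere: far outside
        weird = np.ones((3, gm.n_sites), dtype=np.int8)
        data = np.vstack([gm.data, weird])
        big = GenotypeMatrix(
            gm.sample_ids + ["w1", "w2", "w3"],
            data,
            gm.columns,
            gm.minor_alleles,
            gm.major_alleles,
        )
        first = pca(big, 10)
        rerun = remove_outliers_and_rerun(first, big, sd_threshold=2.7)
        flagged = set(np.array(big.sample_ids)[rerun.outlier_flags])
        assert flagged == {"w1", "w2", "w3"}
        assert len(rerun.sample_ids) == 50

    def test_no_outliers_returns_equivalent_result(self):
        gm, _ = two_pop_gm(seed=506)
        first = pca(gm, 10)
        rerun = remove_outliers_and_rerun(first, gm, sd_threshold=50.0)
        assert not rerun.outlier_flags.any()
        assert np.allclose(rerun.coordinates, first.coordinates)

    def test_mass_flagging_aborts(self):
        gm, _ = two_pop_gm(seed=507)
        first = pca(gm, 10)
        with pytest.raises(ValueError, match="outlier"):
            remove_outliers_and_rerun(first, gm, sd_threshold=0.1)


class TestAncestry:
    def match_columns(self, Q, Q_true):
        K = Q.shape[1]
        perm = min(
            itertools.permutations(range(K)),
            key=lambda p: np.abs(Q[:, list(p)] - Q_true).mean(),
        )
        return Q[:, list(perm)]

    def test_two_population_recovery_with_admixed_sample(self):
        gm, haps = two_pop_gm(seed=400, admixture=((0.5, 0.5),))
        res = nmf_ancestry(gm, 2, seed=1)
        Q = self.match_columns(res.Q, haps.Q_true)
        assert np.abs(Q[:60] - haps.Q_true[:60]).mean() < 0.05
        assert abs(Q[60, 0] - 0.5) <= 0.1

    def test_loss_monotone_and_rows_on_simplex(self):
        gm, _ = two_pop_gm(seed=401, n=15)
        res = nmf_ancestry(gm, 3, seed=2, n_restarts=2, max_iter=50)
        assert all(
            a >= b - 1e-9 for a, b in zip(res.loss_history, res.loss_history[1:])
        )
        assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-9)
        assert (res.Q >= 0).all() and (res.G >= 0).all()

    def test_same_seed_reproduces_the_factorization(self):
        gm, _ = two_pop_gm(seed=402, n=15)
        a = nmf_ancestry(gm, 2, seed=3, n_restarts=2, max_iter=60)
        b = nmf_ancestry(gm, 2, seed=3, n_restarts=2, max_iter=60)
        assert np.array_equal(a.Q, b.Q) and np.array_equal(a.G, b.G)
        assert a.loss == b.loss

    def test_k_bounds_enforced(self):
        gm, _ = two_pop_gm(seed=403, n=3)
        with pytest.raises(ValueError):
            nmf_ancestry(gm, 1, seed=0)
        with pytest.raises(ValueError):
            nmf_ancestry(gm, 6, seed=0)


class TestDistancesAndNJ:
    def test_snp_distance_trivial_cases(self):
        aln = AlignmentMatrix.from_strings(
            ["a", "b", "c"], ["ACGTA", "ACGTT", "NCGTT"]
        )
        d = pairwise_snp_distance(aln)
        # the N in row c masks its first column from both comparisons
        assert d[0, 1] == 1 and d[1, 2] == 0 and d[0, 2] == 1
        assert np.allclose(d, d.T)

    @pytest.mark.parametrize("seed", range(3))
    def test_snp_distance_matches_exhaustive_count(self, seed):
        rng = random.Random(seed)
        rows = [
            "".join(rng.choice("ACGTN-") for _ in range(50)) for _ in range(10)
        ]
        aln = AlignmentMatrix.from_strings([f"s{i}" for i in range(10)], rows)
        d = pairwise_snp_distance(aln)
        for i in range(10):
            for j in range(10):
                expected = sum(
                    1
                    for a, b in zip(rows[i], rows[j])
                    if a in "ACGT" and b in "ACGT" and a != b
                )
                assert d[i, j] == expected

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        lengths = {min(u, v, key=lambda x: x): w for u, v, w in tree.edges}
        assert lengths[0] == pytest.approx(3.0)  # (5+9-8)/2
        assert lengths[1] == pytest.approx(2.0)
        assert lengths[2] == pytest.approx(6.0)

    def random_additive_tree(self, rng, n_leaves):
        taxa = [f"t{i}" for i in range(n_leaves)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_leaves,
            rng=rng,
        )
        for leaf, name in zip(tree.leaf_node_iter(), taxa):
            leaf.taxon.label = name
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = rng.uniform(0.1, 1.0)
        return tree

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_distances_recover_the_topology(self, seed):
        rng = random.Random(seed)
        n_leaves = rng.randint(10, 30)
        true = self.random_additive_tree(rng, n_leaves)
        pdm = true.phylogenetic_distance_matrix()
        taxa = sorted(true.taxon_namespace, key=lambda t: t.label)
        names = [t.label for t in taxa]
        d = np.array(
            [[pdm.distance(a, b) for b in taxa] for a in taxa]
        )
        est = neighbor_joining(d, names)
        assert unrooted_rf(est.newick(), true.as_string(schema="newick"), names) == 0

    def test_tie_break_is_deterministic(self):
        # ultrametric 4-taxon matrix with two equidistant cherries
        d = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        n1 = neighbor_joining(d, list("abcd")).newick()
        n2 = neighbor_joining(d, list("abcd")).newick()
        assert n1 == n2

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(np.zeros((2, 2)))

    def test_negative_branch_lengths_clamped_with_warning(self):
        # grossly non-additive: the a-b split cannot be realized without a
        # negative internal branch
        d = np.array(
            [[0, 10, 1, 1], [10, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]],
            dtype=float,
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(d)
        assert all(w >= 0 for _, _, w in tree.edges)


class TestGroupFst:
    def three_group_alignment(self):
        # groups A and B drawn from one population; group C strongly diverged
        cfg = SimulationConfig(
            seed=600,
            n_samples=24,
            n_populations=2,
            migration=0.01,
            theta=60.0,
            rho_background=40.0,
        )
        aln = variants_to_alignment(simulate_haplotypes(cfg))
        meta = []
        for i, sid in enumerate(aln.sample_ids):
            group = "beer" if i < 12 else ("bread" if i < 24 else "laboratory")
            meta.append(SampleMetadata(sid, group, "unknown"))
        return aln, meta

    def test_diverged_group_sits_on_longest_terminal_branch(self):
        aln, meta = self.three_group_alignment()
        df, tree = group_fst_tree(aln, meta, "source_group")
        assert list(df.columns) == ["beer", "bread", "laboratory"]
        assert np.allclose(df.values, df.values.T)
        assert np.allclose(np.diag(df.values), 0.0)
        assert df.loc["beer", "laboratory"] > df.loc["beer", "bread"]
        leaf_edge = {
            min(u, v): w for u, v, w in tree.edges if min(u, v) < 3
        }
        assert leaf_edge[2] == max(leaf_edge.values())

    def test_small_groups_excluded_with_warning(self):
        aln, meta = self.three_group_alignment()
        meta[0] = SampleMetadata(meta[0].sample_id, "sake", "unknown")
        with pytest.warns(UserWarning, match="excluded"):
            df, _ = group_fst_tree(aln, meta, "source_group")
        assert "sake" not in df.columns

    def test_too_few_groups_rejected(self):
        aln, meta = self.three_group_alignment()
        meta = [SampleMetadata(m.sample_id, "beer", "unknown") for m in meta]
        with pytest.raises(ValueError, match="at least 3"):
            group_fst_tree(aln, meta, "source_group")
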