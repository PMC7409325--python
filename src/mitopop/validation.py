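"""Self-contained validation experiments on synthetic populations.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns measured quantities (recovery errors,
calibration rates, agreement with brute-force recomputation).  They are
the substance behind the acceptance test suite and the
``scripts/acceptance.py`` report; every simulation size is chosen to run
on one CPU in minutes and is documented in the methods note.
"""

from __future__ import annotations

import itertools
import random

import numpy as np

from .align_qc import AlignmentMatrix, filter_missing_samples, impute_positions
from .core_reference import (
    build_core_reference,
    extract_core_sequence,
    shared_gene_set,
)
from .ld_recomb import (
    build_two_locus_table,
    hudson_kaplan_rm,
    interval_intensity,
    maf_filter,
    pairwise_ld,
    recombination_intensity,
)
from .njtree import NJTree, neighbor_joining
from .popgen_stats import (
    VariantTable,
    call_variants,
    fus_Fs,
    hudson_fst,
    summarize_diversity,
    tajimas_D,
)
from .structure import encode_genotypes, nmf_ancestry, pca
from .simulate import (
    SimulationConfig,
    inject_missingness,
    simulate_dataset,
    simulate_haplotypes,
    variants_to_alignment,
)

__all__ = [
    "oracle_agreement",
    "neutrality_calibration",
    "fst_recovery",
    "nj_additive_recovery",
    "pca_separation",
    "ancestry_recovery",
    "recombination_landscape",
    "core_extraction_check",
    "qc_boundary_check",
    "imputation_restoration",
]


# ---------------------------------------------------------------------------
# 1. brute-force agreement on small alignments


def _random_alignment(rng: random.Random, n=8, L=40) -> AlignmentMatrix:
    base = [rng.choice("ACGT") for _ in range(L)]
    rows = []
    for _ in range(n):
        row = list(base)
        for c in range(L):
            r = rng.random()
            if r < 0.10:
                row[c] = rng.choice("ACGT")
            elif r < 0.14:
                row[c] = "N"
            elif r < 0.16:
                row[c] = "-"
        rows.append("".join(row))
    return AlignmentMatrix.from_strings([f"s{i}" for i in range(n)], rows)


def _brute_stats(aln: AlignmentMatrix) -> dict:
    rows = [aln.row_string(i) for i in range(aln.n_samples)]
    n, L = len(rows), len(rows[0])
    bases = set("ACGT")
    S = ts = tv = 0
    pi_cols = []
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
            diff = sum(a != b for a, b in itertools.combinations(obs, 2))
            pi_cols.append(diff / (len(obs) * (len(obs) - 1) / 2))
    diffs = [
        sum(
            1
            for c in range(L)
            if rows[i][c] in bases and rows[j][c] in bases and rows[i][c] != rows[j][c]
        )
        for i, j in itertools.combinations(range(n), 2)
    ]
    keep = [c for c in range(L) if all(r[c] in bases for r in rows)]
    counts: dict[str, int] = {}
    for r in rows:
        h = "".join(r[c] for c in keep)
        counts[h] = counts.get(h, 0) + 1
    p2 = sum((v / n) ** 2 for v in counts.values())
    return {
        "S": S,
        "ts": ts,
        "tv": tv,
        "k": sum(diffs) / len(diffs),
        "pi": sum(pi_cols) / len(pi_cols) if pi_cols else 0.0,
        "h": len(counts),
        "Hd": n * (1 - p2) / (n - 1),
    }


def _brute_rm(variants: VariantTable) -> int:
    bad = []
    for i in range(variants.n_sites):
        for j in range(i + 1, variants.n_sites):
            gi, gj = variants.genotypes[:, i], variants.genotypes[:, j]
            seen = {
                (int(a), int(b)) for a, b in zip(gi, gj) if a >= 0 and b >= 0
            }
            if len(seen) == 4:
                bad.append((i, j))
    if not bad:
        return 0
    gaps = range(variants.n_sites - 1)
    for k in range(1, len(bad) + 1):
        for cuts in itertools.combinations(gaps, k):
            if all(any(l <= c < r for c in cuts) for l, r in bad):
                return k
    return len(bad)


def oracle_agreement(seed: int, n_fixtures: int = 6) -> dict:
    """Max absolute disagreement with brute-force recomputation of S, h,
    Hd, k, π, transitions/transversions, D', r² and Rm on random
    fixtures of at most 10 samples × 50 sites."""
    rng = random.Random(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        aln = _random_alignment(rng, n=rng.randint(6, 10), L=rng.randint(30, 50))
        s = summarize_diversity(aln)
        o = _brute_stats(aln)
        worst = max(
            worst,
            abs(s.n_polymorphic_sites - o["S"]),
            abs(s.transitions - o["ts"]),
            abs(s.transversions - o["tv"]),
            abs(s.n_haplotypes - o["h"]),
            abs(s.gene_diversity - o["Hd"]),
            abs(s.mean_pairwise_differences - o["k"]),
            abs(s.nucleotide_diversity - o["pi"]),
        )
        vt = maf_filter(call_variants(aln), 0.0)
        worst = max(worst, abs(hudson_kaplan_rm(vt)[0] - _brute_rm(vt)))
        for i in range(vt.n_sites):
            for j in range(i + 1, vt.n_sites):
                p = pairwise_ld(vt, i, j)
                if p is None:
                    continue
                gi, gj = vt.genotypes[:, i], vt.genotypes[:, j]
                both = (gi >= 0) & (gj >= 0)
                gi, gj = gi[both], gj[both]
                m = len(gi)
                pA = float((gi == 0).sum()) / m
                pB = float((gj == 0).sum()) / m
                D = float(((gi == 0) & (gj == 0)).sum()) / m - pA * pB
                dmax = (
                    min(pA * (1 - pB), (1 - pA) * pB)
                    if D >= 0
                    else min(pA * pB, (1 - pA) * (1 - pB))
                )
                dprime = abs(D) / dmax if dmax > 0 else 0.0
                r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
                worst = max(
                    worst,
                    abs(p.D_prime - min(dprime, 1.0)),
                    abs(p.r2 - min(r2, 1.0)),
                )
    return {"max_abs_diff": worst}


# ---------------------------------------------------------------------------
# 2. neutrality-test calibration


def neutrality_calibration(
    seed: int,
    n_replicates: int = 1000,
    n: int = 50,
    theta: float = 5.0,
    inner_replicates: int = 300,
) -> dict:
    """Mean Tajima's D and 5%-level rejection rates of D and Fs on neutral
    coalescent data.  D's 5%-level test uses the fixed-S simulation p;
    Fs's uses its conventional 5%-level region p < 0.02."""
    d_values, rej_d, rej_fs = [], 0, 0
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=(seed * 100003 + i) % (2**31),
            n_samples=n,
            theta=theta,
            rho_background=0.0,
        )
        aln = variants_to_alignment(simulate_haplotypes(cfg), coding_only=False)
        taj = tajimas_D(aln, seed=i, n_simulations=inner_replicates)
        if taj is None:
            continue
        d_values.append(taj.D)
        rej_d += taj.p_simulation < 0.05
        fs = fus_Fs(aln, seed=i, n_replicates=inner_replicates)
        rej_fs += fs.p < 0.02
    m = len(d_values)
    return {
        "mean_tajima_D": float(np.mean(d_values)),
        "tajima_rejection_rate": rej_d / m,
        "fu_fs_rejection_rate": rej_fs / m,
        "n_replicates": m,
    }


# ---------------------------------------------------------------------------
# 3. Fst recovery


def fst_recovery(
    seed: int,
    targets=(0.0, 0.05, 0.15),
    n_seeds: int = 20,
    n_per_group: int = 50,
    n_snps: int = 500,
) -> dict:
    """Mean Hudson-Fst estimate per calibrated island-model target.

    theta is set so a replicate segregates ~500 SNPs; recombination is
    high so the SNPs carry many independent genealogies — the check
    targets estimator accuracy, not single-tree sampling noise.
    """
    out = {}
    for target in targets:
        vals = []
        for i in range(n_seeds):
            cfg = SimulationConfig(
                seed=(seed * 7919 + int(target * 1000) * 101 + i) % (2**31),
                n_samples=n_per_group,
                n_populations=2,
                target_fst=target,
                theta=100.0,
                rho_background=150.0,
            )
            aln = variants_to_alignment(simulate_haplotypes(cfg), coding_only=False)
            if aln.n_columns > n_snps:
                aln = AlignmentMatrix(
                    aln.sample_ids,
                    aln.codes[:, :n_snps],
                    aln.column_map[:n_snps],
                )
            vals.append(
                hudson_fst(
                    aln,
                    aln.sample_ids[:n_per_group],
                    aln.sample_ids[n_per_group:],
                )
            )
        out[target] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# 4. NJ exactness on additive trees


def _random_additive_tree(rng: random.Random, n_leaves: int) -> NJTree:
    """Random unrooted binary tree with uniform branch lengths."""
    tree = NJTree([f"t{i}" for i in range(n_leaves)])
    nodes = list(range(n_leaves))
    nxt = n_leaves
    while len(nodes) > 3:
        i = nodes.pop(rng.randrange(len(nodes)))
        j = nodes.pop(rng.randrange(len(nodes)))
        tree.edges.append((i, nxt, rng.uniform(0.1, 1.0)))
        tree.edges.append((j, nxt, rng.uniform(0.1, 1.0)))
        nodes.append(nxt)
        nxt += 1
    hub = nxt
    for k in nodes:
        tree.edges.append((k, hub, rng.uniform(0.1, 1.0)))
    return tree


def _unrooted_rf(newick_a: str, newick_b: str, names) -> int:
    import dendropy

    ns = dendropy.TaxonNamespace(names)
    trees = []
    for nwk in (newick_a, newick_b):
        t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns)
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.update_bipartitions()
        trees.append(t)
    return dendropy.calculate.treecompare.symmetric_difference(*trees)


def nj_additive_recovery(seed: int, n_trees: int = 100) -> dict:
    """Number of random additive trees (10-30 leaves) whose topology NJ
    fails to recover exactly (Robinson-Foulds > 0)."""
    rng = random.Random(seed)
    failures = 0
    for _ in range(n_trees):
        n_leaves = rng.randint(10, 30)
        true = _random_additive_tree(rng, n_leaves)
        d = true.leaf_distances()
        est = neighbor_joining(d, true.taxa)
        if _unrooted_rf(est.newick(), true.newick(), true.taxa) != 0:
            failures += 1
    return {"failures": failures, "n_trees": n_trees}


# ---------------------------------------------------------------------------
# 5/6. structure recovery


def _diverged_pair_gm(seed: int, n: int, admixture=()):
    cfg = SimulationConfig(
        seed=seed,
        n_samples=n,
        n_populations=2,
        migration=0.005,  # effectively fully diverged populations
        theta=60.0,
        rho_background=50.0,
        admixture=admixture,
    )
    haps = simulate_haplotypes(cfg)
    gm = encode_genotypes(
        maf_filter(call_variants(variants_to_alignment(haps)), 0.10)
    )
    return gm, haps


def pca_separation(seed: int, n_per_pop: int = 30) -> dict:
    """PC1 sign classification errors on two well-separated populations."""
    gm, _ = _diverged_pair_gm(seed, n_per_pop)
    res = pca(gm, 10)
    pc1 = res.coordinates[:, 0]
    a, b = pc1[:n_per_pop], pc1[n_per_pop:]
    errors = min(
        int((a > 0).sum() + (b <= 0).sum()), int((a <= 0).sum() + (b > 0).sum())
    )
    return {
        "pc1_errors": errors,
        "variance_fraction_sum": float(res.variance_fractions.sum()),
        "n_samples": gm.n_samples,
    }


def ancestry_recovery(seed: int, n_per_pop: int = 30) -> dict:
    """K=2 admixture-coefficient recovery with one true 50/50 sample."""
    gm, haps = _diverged_pair_gm(seed, n_per_pop, admixture=((0.5, 0.5),))
    res = nmf_ancestry(gm, 2, seed=seed)
    n2 = 2 * n_per_pop
    best = None
    for perm in itertools.permutations(range(2)):
        err = np.abs(res.Q[:n2][:, list(perm)] - haps.Q_true[:n2]).mean()
        dev = abs(res.Q[n2, list(perm)[0]] - 0.5)
        if best is None or err < best[0]:
            best = (float(err), float(dev))
    return {"q_error_unadmixed": best[0], "admixed_deviation": best[1]}


# ---------------------------------------------------------------------------
# 7. recombination landscape


def recombination_landscape(
    seed: int,
    n_replicates: int = 50,
    table=None,
    table_reps: int = 40000,
) -> dict:
    """Hotspot top-ranking rate and the no-recombination Rm sanity rate.

    A 10x recombination hotspot is planted in one intergenic spacer; a
    replicate scores a hit when that spacer attains the maximum relative
    intensity among all intergenic intervals.  Separately, datasets
    simulated without recombination must always give Rm = 0.
    """
    if table is None:
        table = build_two_locus_table(n=24, reps=table_reps, seed=seed)
    layout = tuple((800, 300) for _ in range(6))
    hot_idx = 2
    hits = 0
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=(seed * 4007 + i) % (2**31),
            n_samples=100,
            theta=80.0,
            rho_background=16.0,
            gene_layout=layout,
            hotspot_multipliers={hot_idx: 10.0},
        )
        vt = maf_filter(
            call_variants(variants_to_alignment(simulate_haplotypes(cfg))), 0.10
        )
        prof = recombination_intensity(
            vt, table, seed=i, max_span_sites=16, max_span_bp=1200,
            n_subsample_draws=8,
        )
        spacers = cfg.intergenic_intervals()
        lams = [interval_intensity(prof, sp) for sp in spacers]
        hot = lams[hot_idx]
        others = [l for k, l in enumerate(lams) if k != hot_idx and l is not None]
        hits += int(hot is not None and bool(others) and hot >= max(others))

    rm_zero = 0
    n_rm = 20
    for i in range(n_rm):
        cfg = SimulationConfig(
            seed=(seed * 6007 + i) % (2**31),
            n_samples=30,
            theta=30.0,
            rho_background=0.0,
        )
        vt = call_variants(variants_to_alignment(simulate_haplotypes(cfg)))
        rm_zero += hudson_kaplan_rm(vt)[0] == 0
    return {
        "hotspot_top_rate": hits / n_replicates,
        "rm_zero_rate": rm_zero / n_rm,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# 8. core extraction


def core_extraction_check(seed: int) -> dict:
    """The standard rescue/deletion fixture: the deleted gene (and only
    it) leaves the shared set, the rescued region's coordinates are
    exact, and the N-fill provenance is correct."""
    layout = tuple((180 + 20 * i, 60) for i in range(8))
    cfg = SimulationConfig(
        seed=seed,
        n_samples=20,
        theta=8.0,
        rho_background=5.0,
        gene_layout=layout,
        forced_annotation_dropout=((3, "COX2"),),
        forced_gene_deletion=((7, "ATP6"),),
    )
    ds = simulate_dataset(cfg)
    genes = shared_gene_set(ds.genomes, ds.reference)
    shared_ok = genes == [
        "COX1", "COX2", "COX3", "COB", "ATP8", "ATP9", "VAR1"
    ]
    core = build_core_reference(ds.reference, genes)
    cs = extract_core_sequence(ds.genomes[3], core)
    idx = [r.gene_name for r in core.regions].index("COX2")
    hit = cs.hits[idx]
    rescue_ok = (
        cs.provenance[idx] == "rescued"
        and hit is not None
        and (hit.start, hit.end) == ds.gene_truth["S003"]["COX2"]
    )
    # a genome missing a gene entirely, relative to a core that kept it
    full_core = build_core_reference(ds.reference, list(cfg.gene_names))
    cs7 = extract_core_sequence(ds.genomes[7], full_core)
    j = [r.gene_name for r in full_core.regions].index("ATP6")
    nfill_ok = (
        cs7.provenance[j] == "missing"
        and cs7.region_seqs[j] == "N" * full_core.regions[j].length
    )
    return {
        "shared_set_correct": int(shared_ok),
        "rescue_coordinates_exact": int(rescue_ok),
        "n_fill_provenance_correct": int(nfill_ok),
    }


# ---------------------------------------------------------------------------
# 9/10. QC semantics and imputation


def qc_boundary_check(seed: int) -> dict:
    """Exactly-10% missing retained; anything above dropped."""
    at = "N" * 100 + "A" * 900
    above = "N" * 101 + "A" * 899
    aln = AlignmentMatrix.from_strings(
        ["at_threshold", "above", "clean"], [at, above, "A" * 1000]
    )
    kept, report = filter_missing_samples(aln, 0.10)
    return {
        "retained_at_threshold": int("at_threshold" in kept.sample_ids),
        "dropped_above_threshold": int("above" in report.dropped_samples),
    }


def imputation_restoration(
    seed: int, n: int = 50, length: int = 2000, rate: float = 0.05
) -> dict:
    """Fraction of imputable injected Ns restored to the true base on a
    tree-structured alignment (n samples x `length` coding columns)."""
    cfg = SimulationConfig(
        seed=seed,
        n_samples=n,
        theta=15.0,
        rho_background=4.0,
        gene_layout=tuple((length // 8, 0) for _ in range(8)),
    )
    ds = simulate_dataset(cfg)
    core = build_core_reference(ds.reference, list(cfg.gene_names))
    rows = [
        "".join(ds.genomes[i].feature_sequence(f) for f in ds.genomes[i].features)
        for i in range(n)
    ]
    aln = AlignmentMatrix.from_strings(ds.sample_ids, rows)
    masked, mask = inject_missingness(aln, rate, seed=seed + 1)
    out = impute_positions(masked)
    imputed = (out.codes != ord("N")) & mask
    restored = float((out.codes[imputed] == aln.codes[imputed]).mean())
    return {
        "restoration_rate": restored,
        "n_imputed": int(imputed.sum()),
        "n_masked": int(mask.sum()),
    }
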