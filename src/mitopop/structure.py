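"""Population-structure analyses for homoplasmic mitotype data.

Samples are haploid (each isolate one phased haplotype), so genotypes are
0/1 major/minor codes.  The module provides:

* PCA with allele-frequency variance normalization (each site centered
  and divided by sqrt(p(1−p)), missing set to 0 after centering), plus a
  single outlier-removal rerun (|coordinate| > 6 SD on any of the top 3
  PCs) to zoom into the dense part of the cloud;
* individual-ancestry estimation by sparse nonnegative matrix
  factorization: minimize ‖X − QG‖² + α‖Q‖² with Q rows on the simplex
  and G ≥ 0, by exact alternating block minimization;
* neighbor-joining trees on pairwise SNP differences, and NJ trees built
  from matrices of pairwise Hudson Fst between labelled groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .njtree import NJTree, neighbor_joining
from .popgen_stats import VariantTable, hudson_fst

__all__ = [
    "GenotypeMatrix",
    "PCAResult",
    "AncestryResult",
    "encode_genotypes",
    "pca",
    "remove_outliers_and_rerun",
    "nmf_ancestry",
    "pairwise_snp_distance",
    "neighbor_joining",
    "group_fst_tree",
]

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenotypeMatrix:
    """samples × biallelic sites; 0 = major allele, 1 = minor, −1 = missing."""

    sample_ids: list[str]
    data: np.ndarray
    columns: np.ndarray
    minor_alleles: list[str]
    major_alleles: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def minor_allele_frequencies(self) -> np.ndarray:
        obs = self.data >= 0
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.sum(0) > 0, (self.data == 1).sum(0) / np.maximum(obs.sum(0), 1), 0.0
            )

    def subset(self, keep_idx) -> "GenotypeMatrix":
        keep_idx = list(keep_idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in keep_idx],
            self.data[keep_idx].copy(),
            self.columns.copy(),
            list(self.minor_alleles),
            list(self.major_alleles),
        )


def encode_genotypes(variants: VariantTable) -> GenotypeMatrix:
    """0/1 encoding of MAF-filtered biallelic sites.

    The minor allele is the lower-frequency one; at exact 50/50 ties the
    alphabetically later allele is minor.  Variant tables already order
    alleles by descending count with alphabetical tie-breaks, so allele
    index 1 is the minor allele directly.
    """
    data = variants.genotypes.copy()
    if (data > 1).any():
        raise ValueError("encode_genotypes requires biallelic (MAF-filtered) sites")
    majors, minors = [], []
    for a in variants.alleles:
        if len(a) != 2:
            raise ValueError("encode_genotypes requires biallelic sites")
        majors.append(a[0])
        minors.append(a[1])
    return GenotypeMatrix(
        list(variants.sample_ids), data, variants.columns.copy(), minors, majors
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    coordinates: np.ndarray  # samples x n_pcs
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray  # over all sample-space components
    outlier_flags: np.ndarray
    sample_ids: list[str]
    n_pcs: int


def _normalized_matrix(gm: GenotypeMatrix, variance_normalize: bool = True):
    X = gm.data.astype(float)
    miss = gm.data < 0
    Xm = np.ma.masked_array(X, miss)
    p = Xm.mean(axis=0).filled(0.0)
    X = X - p
    X[miss] = 0.0
    if variance_normalize:
        scale = np.sqrt(p * (1.0 - p))
        keep = scale > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance sites")
        X = X[:, keep] / scale[keep]
    else:
        keep = X.std(axis=0) > 0
        X = X[:, keep]
    return X


def pca(gm: GenotypeMatrix, n_pcs: int = 10, variance_normalize: bool = True) -> PCAResult:
    """Principal components of the normalized genotype matrix.

    Coordinates are the sample projections; variance fractions are the
    eigenvalue shares over all sample-space components (they sum to 1).
    """
    if gm.n_samples < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 samples")
    X = _normalized_matrix(gm, variance_normalize)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / max(gm.n_samples - 1, 1)
    fractions = eig / eig.sum() if eig.sum() > 0 else eig
    k = min(n_pcs, len(s))
    coords = U[:, :k] * s[:k]
    if k < n_pcs:
        coords = np.pad(coords, ((0, 0), (0, n_pcs - k)))
    return PCAResult(
        coordinates=coords,
        eigenvalues=eig,
        variance_fractions=fractions,
        outlier_flags=np.zeros(gm.n_samples, dtype=bool),
        sample_ids=list(gm.sample_ids),
        n_pcs=n_pcs,
    )


def remove_outliers_and_rerun(
    result: PCAResult,
    gm: GenotypeMatrix,
    sd_threshold: float = 6.0,
    top_pcs: int = 3,
) -> PCAResult:
    """Flag samples beyond ``sd_threshold`` standard deviations on any of
    the top PCs, remove them, and rerun the PCA once (the published
    analyses show a single outlier-exclusion rerun)."""
    coords = result.coordinates[:, :top_pcs]
    sd = coords.std(axis=0)
    if np.all(sd == 0):
        warnings.warn("zero variance on all top PCs; no outliers")
        return result
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(coords) / np.where(sd > 0, sd, np.inf)
    flags = (z > sd_threshold).any(axis=1)
    if flags.sum() > 0.2 * gm.n_samples:
        raise ValueError(
            f"{int(flags.sum())} of {gm.n_samples} samples flagged as outliers; "
            "check the input before rerunning"
        )
    if not flags.any():
        out = PCAResult(
            result.coordinates,
            result.eigenvalues,
            result.variance_fractions,
            flags,
            list(result.sample_ids),
            result.n_pcs,
        )
        return out
    keep = np.nonzero(~flags)[0]
    rerun = pca(gm.subset(keep), result.n_pcs)
    rerun.outlier_flags = flags
    rerun.sample_ids = [gm.sample_ids[i] for i in keep]
    return rerun


# ---------------------------------------------------------------------------
# ancestry by sparse NMF


@dataclass
class AncestryResult:
    K: int
    Q: np.ndarray  # samples x K, rows on the simplex
    G: np.ndarray  # K x (2 * sites), nonnegative
    loss: float
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)


def _simplex_ls_rows(X: np.ndarray, G: np.ndarray, alpha: float) -> np.ndarray:
    """Exact per-row solution of min ‖X − QG‖² + α‖Q‖², Q rows on the simplex.

    Active-set enumeration: for each candidate support the
    equality-constrained KKT system is solved for all rows at once, and
    each row keeps its best feasible support.  Exact for K ≤ ~8.
    """
    n, K = X.shape[0], G.shape[0]
    A = G @ G.T + alpha * np.eye(K)  # K x K, PD
    B = X @ G.T  # n x K
    best_q = np.zeros((n, K))
    best_obj = np.full(n, np.inf)
    for r in range(1, K + 1):
        for support in itertools.combinations(range(K), r):
            s = list(support)
            M = np.zeros((r + 1, r + 1))
            M[:r, :r] = A[np.ix_(s, s)]
            M[:r, r] = 1.0
            M[r, :r] = 1.0
            rhs = np.zeros((r + 1, n))
            rhs[:r] = B[:, s].T
            rhs[r] = 1.0
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                continue
            q_s = sol[:r].T  # n x r
            feasible = (q_s >= -1e-12).all(axis=1)
            if not feasible.any():
                continue
            q_full = np.zeros((n, K))
            q_full[:, s] = np.clip(q_s, 0.0, None)
            # objective: ½ qAqᵀ − q·b (constant ‖X‖² dropped); scaled by 2
            obj = np.einsum("ij,jk,ik->i", q_full, A, q_full) - 2 * np.einsum(
                "ij,ij->i", q_full, B
            )
            better = feasible & (obj < best_obj - 1e-12)
            best_obj[better] = obj[better]
            best_q[better] = q_full[better]
    # renormalize away the numerical clip
    best_q /= best_q.sum(axis=1, keepdims=True)
    return best_q


def _nnls_columns(Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Exact column solutions of min ‖X − QG‖², G ≥ 0 (support enumeration)."""
    K = Q.shape[1]
    A = Q.T @ Q + 1e-12 * np.eye(K)
    B = Q.T @ X  # K x m
    m = X.shape[1]
    best_g = np.zeros((K, m))
    best_obj = np.full(m, np.inf)
    for r in range(1, K + 1):
        for support in itertools.combinations(range(K), r):
            s = list(support)
            try:
                sol = np.linalg.solve(A[np.ix_(s, s)], B[s])
            except np.linalg.LinAlgError:
                continue
            feasible = (sol >= -1e-12).all(axis=0)
            if not feasible.any():
                continue
            g_full = np.zeros((K, m))
            g_full[s] = np.clip(sol, 0.0, None)
            obj = np.einsum("km,kj,jm->m", g_full, A, g_full) - 2 * np.einsum(
                "km,km->m", g_full, B
            )
            better = feasible & (obj < best_obj - 1e-12)
            best_obj[better] = obj[better]
            best_g[:, better] = g_full[:, better]
    return best_g


def nmf_ancestry(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    alpha: float = 10.0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> AncestryResult:
    """Ancestry proportions by sparse nonnegative matrix factorization.

    Sites are one-hot expanded to two columns (major/minor frequency),
    missing entries mean-imputed per site.  The objective
    ‖X − QG‖² + α‖Q‖² is minimized by exact alternating block updates
    (simplex-constrained rows of Q, nonnegative columns of G); the best of
    ``n_restarts`` seeded restarts is returned.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if K >= gm.n_samples:
        raise ValueError("K must be smaller than the sample count")
    data = gm.data.astype(float)
    miss = gm.data < 0
    col_mean = np.ma.masked_array(data, miss).mean(axis=0).filled(0.0)
    data[miss] = np.take(col_mean, np.nonzero(miss)[1])
    X = np.concatenate([1.0 - data, data], axis=1)  # n x 2p

    best: AncestryResult | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng((seed * 7919 + restart) % (2**31))
        Q = rng.dirichlet(np.ones(K), size=gm.n_samples)
        G = rng.uniform(0.0, 1.0, size=(K, X.shape[1]))
        prev = np.inf
        history: list[float] = []
        for _ in range(max_iter):
            Q = _simplex_ls_rows(X, G, alpha)
            G = _nnls_columns(Q, X)
            loss = float(((X - Q @ G) ** 2).sum() + alpha * (Q**2).sum())
            history.append(loss)
            if prev - loss < tol * max(prev, 1.0):
                prev = loss
                break
            prev = loss
        if best is None or prev < best.loss:
            best = AncestryResult(K, Q, G, prev, seed, list(gm.sample_ids), history)
    return best


# ---------------------------------------------------------------------------
# distances and trees


def pairwise_snp_distance(aln) -> np.ndarray:
    """Counts of differing columns per sample pair (both bases in ACGT)."""
    codes = aln.codes
    n = codes.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    valid = np.isin(codes, _BASE_CODES)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        row = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def group_fst_tree(aln, metadata, grouping: str = "source_group"):
    """Pairwise Hudson Fst between labelled groups plus the NJ tree on it.

    Groups with fewer than 2 samples are excluded with a warning; samples
    labelled "unknown" are ignored.  Negative Fst estimates are kept in
    the matrix but clamped to 0 for tree building (NJ needs distances).
    Returns ``(fst DataFrame, NJTree)``.
    """
    present = set(aln.sample_ids)
    groups: dict[str, list[str]] = {}
    for m in metadata:
        label = getattr(m, grouping)
        if label != "unknown" and m.sample_id in present:
            groups.setdefault(label, []).append(m.sample_id)
    for label in [g for g, members in groups.items() if len(members) < 2]:
        warnings.warn(f"group {label!r} has <2 samples; excluded")
        del groups[label]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups with >= 2 samples")
    labels = sorted(groups)
    k = len(labels)
    fst = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = hudson_fst(aln, groups[labels[i]], groups[labels[j]])
            fst[i, j] = fst[j, i] = np.nan if v is None else v
    df = pd.DataFrame(fst, index=labels, columns=labels)
    dist = np.nan_to_num(np.clip(fst, 0.0, None))
    tree = neighbor_joining(dist, labels)
    return df, tree
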