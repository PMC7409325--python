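"""Summary statistics and neutrality tests for core alignments.

Conventions (matching the classic DNAsp-style treatment of haploid,
phased mitotype data):

* a column is polymorphic iff at least two distinct bases of {A,C,G,T}
  are observed there — ``N`` and ``-`` are ignored for allele calling;
* haplotyping uses complete deletion (columns containing any N or ``-``
  are excluded before rows are compared);
* mean pairwise differences k and nucleotide diversity π use pairwise
  deletion (each pair compared over the columns where both carry a base);
* Fst between groups is Hudson's 1 − Hw/Hb on mean pairwise differences,
  with the two groups weighted equally in Hw by default.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .coalescent import sample_ewens_k

__all__ = [
    "VariantTable",
    "DiversitySummary",
    "TajimaResult",
    "FuFsResult",
    "call_variants",
    "summarize_diversity",
    "tajimas_D",
    "fus_Fs",
    "hudson_fst",
    "tajima_constants",
]

_N = ord("N")
_GAP = ord("-")
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class VariantTable:
    """Segregating sites: core coordinates, per-site allele lists (ordered by
    descending count, ties alphabetical) and per-sample allele indices
    (−1 = unread/gap)."""

    sample_ids: list[str]
    columns: np.ndarray
    alleles: list[list[str]]
    genotypes: np.ndarray  # samples x sites, int8

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=int)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.columns)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allele_counts(self, s: int) -> list[int]:
        g = self.genotypes[:, s]
        return [int((g == i).sum()) for i in range(len(self.alleles[s]))]

    def missing_count(self, s: int) -> int:
        return int((self.genotypes[:, s] < 0).sum())

    def minor_allele_frequency(self, s: int) -> float:
        counts = self.allele_counts(s)
        total = sum(counts)
        if total == 0:
            return 0.0
        return (total - max(counts)) / total if len(counts) > 1 else 0.0

    def pair_classification(self, s: int) -> list[str]:
        """'transition'/'transversion' per unordered observed allele pair."""
        out = []
        a = self.alleles[s]
        for i in range(len(a)):
            for j in range(i + 1, len(a)):
                out.append(
                    "transition"
                    if frozenset((a[i], a[j])) in _TRANSITIONS
                    else "transversion"
                )
        return out

    def transition_transversion_counts(self) -> tuple[int, int]:
        ts = tv = 0
        for s in range(self.n_sites):
            for cls in self.pair_classification(s):
                if cls == "transition":
                    ts += 1
                else:
                    tv += 1
        return ts, tv


def call_variants(aln) -> VariantTable:
    """Census the polymorphic columns of an alignment.

    A triallelic A/G/T column contributes one transition pair (A/G) and
    two transversion pairs (A/T, G/T) to the pair classification.
    """
    codes = aln.codes
    if codes.size == 0:
        raise ValueError("empty alignment")
    counts = np.stack([(codes == b).sum(axis=0) for b in _BASE_CODES])  # 4 x L
    poly = (counts > 0).sum(axis=0) >= 2
    cols = np.nonzero(poly)[0]
    alleles, geno_cols = [], []
    for c in cols:
        cnt = counts[:, c]
        order = sorted(
            (i for i in range(4) if cnt[i] > 0),
            key=lambda i: (-cnt[i], chr(_BASE_CODES[i])),
        )
        alleles.append([chr(_BASE_CODES[i]) for i in order])
        lut = np.full(256, -1, dtype=np.int8)
        for rank, i in enumerate(order):
            lut[_BASE_CODES[i]] = rank
        geno_cols.append(lut[codes[:, c]])
    genotypes = (
        np.stack(geno_cols, axis=1)
        if geno_cols
        else np.zeros((codes.shape[0], 0), np.int8)
    )
    return VariantTable(
        list(aln.sample_ids), aln.column_map[cols], alleles, genotypes
    )


@dataclass
class DiversitySummary:
    n_sequences: int
    length_bp: int
    n_polymorphic_sites: int
    n_haplotypes: int
    gene_diversity: float
    gene_diversity_sd: float
    mean_pairwise_differences: float
    mean_pairwise_differences_sd: float
    nucleotide_diversity: float
    nucleotide_diversity_sd: float
    transitions: int
    transversions: int
    base_composition: dict[str, float]


def _column_diff_pairs(codes: np.ndarray):
    """Per-column observed sample count and differing-pair count."""
    counts = np.stack([(codes == b).sum(axis=0) for b in _BASE_CODES])
    nc = counts.sum(axis=0)
    pairs = nc * (nc - 1) // 2
    same = (counts * (counts - 1) // 2).sum(axis=0)
    return nc, pairs - same


def summarize_diversity(aln) -> DiversitySummary:
    """Every Table-1-style quantity for one alignment."""
    codes = aln.codes
    n, L = codes.shape
    if n < 2:
        raise ValueError("need at least 2 sequences")

    # haplotypes: complete deletion of columns holding any N or gap
    complete = ~((codes == _N) | (codes == _GAP)).any(axis=0)
    hap_rows = [codes[i, complete].tobytes() for i in range(n)]
    hap_counts: dict[bytes, int] = {}
    for r in hap_rows:
        hap_counts[r] = hap_counts.get(r, 0) + 1
    h = len(hap_counts)
    p = np.array(list(hap_counts.values())) / n
    sum2, sum3 = float((p**2).sum()), float((p**3).sum())
    hd = n * (1.0 - sum2) / (n - 1)
    # Nei's sampling variance of gene diversity
    var_hd = (
        2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    var_hd = max(var_hd, 0.0)

    nc, diff = _column_diff_pairs(codes)
    total_pairs = n * (n - 1) / 2.0
    k = float(diff.sum()) / total_pairs
    # Tajima's total (stochastic + sampling) variance of the mean number of
    # pairwise differences: V(k) = b1 k + b2 k^2
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    var_k = b1 * k + b2 * k * k
    usable = nc >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(usable, diff / np.maximum(nc * (nc - 1) / 2.0, 1.0), 0.0)
    L_pi = int(usable.sum())
    pi = float(per_site[usable].mean()) if L_pi else 0.0
    sd_pi = math.sqrt(var_k) / L_pi if L_pi else 0.0

    base_counts = {b: int((codes == ord(b)).sum()) for b in "ACGT"}
    total_bases = sum(base_counts.values())
    comp = {
        b: (c / total_bases if total_bases else 0.0) for b, c in base_counts.items()
    }
    variants = call_variants(aln)
    ts, tv = variants.transition_transversion_counts()
    return DiversitySummary(
        n_sequences=n,
        length_bp=L,
        n_polymorphic_sites=variants.n_sites,
        n_haplotypes=h,
        gene_diversity=hd,
        gene_diversity_sd=math.sqrt(var_hd),
        mean_pairwise_differences=k,
        mean_pairwise_differences_sd=math.sqrt(max(var_k, 0.0)),
        nucleotide_diversity=pi,
        nucleotide_diversity_sd=sd_pi,
        transitions=ts,
        transversions=tv,
        base_composition=comp,
    )


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalization constants a1..e2 for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class TajimaResult:
    D: float
    p_beta: float
    p_simulation: float | None
    S: int
    k: float
    theta_w: float


def _tajima_D_from(n: int, S: int, k: float) -> float:
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (k - S / c["a1"]) / denom


def _beta_p(D: float, n: int) -> float:
    """Two-sided p under Tajima's beta approximation of the null density."""
    from scipy.stats import beta as beta_dist

    c = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    bet = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = beta_dist.cdf(x, bet, alpha)
    return 2.0 * min(cdf, 1.0 - cdf)


def tajimas_D(aln, seed: int | None = None, n_simulations: int = 10000) -> TajimaResult | None:
    """Tajima's D with two p-values: beta approximation and, when a seed is
    given, coalescent simulation at the observed n and S (fixed-S neutral
    replicates).  Returns None when there are no segregating sites."""
    codes = aln.codes
    n = codes.shape[0]
    variants = call_variants(aln)
    S = variants.n_sites
    if S == 0:
        warnings.warn("no segregating sites: Tajima's D undefined")
        return None
    _, diff = _column_diff_pairs(codes)
    k = float(diff.sum()) / (n * (n - 1) / 2.0)
    D = _tajima_D_from(n, S, k)
    p_sim = None
    if seed is not None and n_simulations > 0:
        rng = random.Random(seed)
        null = [
            _tajima_D_from(n, S, _fixed_s_pairwise_k(n, S, rng))
            for _ in range(n_simulations)
        ]
        lo = sum(d <= D for d in null) / len(null)
        hi = sum(d >= D for d in null) / len(null)
        p_sim = min(1.0, 2.0 * min(lo, hi))
    c = tajima_constants(n)
    return TajimaResult(D, _beta_p(D, n), p_sim, S, k, S / c["a1"])


def _fixed_s_pairwise_k(n: int, S: int, rng: random.Random) -> float:
    """Mean pairwise differences of one neutral replicate carrying exactly
    S segregating mutations (multinomial placement by branch length)."""
    import bisect as _bisect

    n_nodes = 2 * n - 1
    parent = [0] * n_nodes
    times = [0.0] * n_nodes
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.expovariate(k * (k - 1) * 0.5)
        a = active.pop(rng.randrange(len(active)))
        b = active.pop(rng.randrange(len(active)))
        parent[a] = nxt
        parent[b] = nxt
        times[nxt] = t
        active.append(nxt)
        nxt += 1
    cum = []
    acc = 0.0
    for v in range(n_nodes - 1):
        acc += times[parent[v]] - times[v]
        cum.append(acc)
    sz = [1] * n + [0] * (n - 1)
    for v in range(n_nodes - 1):
        sz[parent[v]] += sz[v]
    tot = 0.0
    for _ in range(S):
        e = min(_bisect.bisect_right(cum, rng.random() * acc), n_nodes - 2)
        tot += sz[e] * (n - sz[e])
    return tot / (n * (n - 1) / 2.0)


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=8)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind, |s(n, k)| for k=0..n."""
    row = [1]
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return tuple(row)


@lru_cache(maxsize=8)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    return tuple(
        math.log(v) if v > 0 else -math.inf for v in _stirling_row(n)
    )


def _ewens_tail_float(n: int, theta: float, k_obs: int) -> float:
    """Pr(K >= k_obs | theta) in float log-space (for null replicates)."""
    lr = _log_stirling_row(n)
    lt = math.log(theta)
    logdenom = sum(math.log(theta + i) for i in range(n))
    terms = np.array([lr[k] + k * lt - logdenom for k in range(1, n + 1)])
    probs = np.exp(terms - terms.max())
    probs /= probs.sum()
    return float(probs[k_obs - 1 :].sum())


def _neutral_K_khat(n: int, theta: float, rng: random.Random):
    """One neutral coalescent replicate: haplotype count K and mean pairwise
    differences k̂ under the infinite-sites model (no recombination).

    Node ids are topological (every parent id exceeds its children's), so
    subtree sizes accumulate in a single ascending pass.
    """
    import bisect as _bisect

    n_nodes = 2 * n - 1
    parent = [0] * n_nodes
    times = [0.0] * n_nodes
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.expovariate(k * (k - 1) * 0.5)
        i = rng.randrange(len(active))
        a = active.pop(i)
        j = rng.randrange(len(active))
        b = active.pop(j)
        parent[a] = nxt
        parent[b] = nxt
        times[nxt] = t
        active.append(nxt)
        nxt += 1
    lens = [times[parent[v]] - times[v] for v in range(n_nodes - 1)]
    total = sum(lens)
    lam = 0.5 * theta * total
    # Poisson draw
    m, p, thresh = 0, 1.0, math.exp(-lam)
    while True:
        p *= rng.random()
        if p <= thresh:
            break
        m += 1
    if m == 0:
        return 1, 0.0
    cum = []
    acc = 0.0
    for L in lens:
        acc += L
        cum.append(acc)
    mutcnt = [0] * (n_nodes - 1)
    for _ in range(m):
        e = _bisect.bisect_right(cum, rng.random() * total)
        mutcnt[min(e, n_nodes - 2)] += 1
    sz = [1] * n + [0] * (n - 1)
    for v in range(n_nodes - 1):
        sz[parent[v]] += sz[v]
    khat = 0.0
    for v, c in enumerate(mutcnt):
        if c:
            khat += c * sz[v] * (n - sz[v])
    khat *= 2.0 / (n * (n - 1))
    # haplotype classes: cut mutated edges, merge through the rest
    uf = list(range(n_nodes))

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for v in range(n_nodes - 1):
        if not mutcnt[v]:
            uf[find(v)] = find(parent[v])
    k_count = len({find(v) for v in range(n)})
    return k_count, khat


def ewens_k_tail_probability(n: int, theta: float, k_obs: int) -> float:
    """Pr(K >= k_obs) under the Ewens sampling formula, exactly (n <= 200)."""
    if n > 200:
        raise ValueError("exact Ewens tail limited to n <= 200")
    th = Fraction(theta).limit_denominator(10**12)
    row = _stirling_row(n)
    denom = Fraction(1)
    for i in range(n):
        denom *= th + i
    num = Fraction(0)
    power = th**k_obs
    for k in range(k_obs, n + 1):
        num += row[k] * power
        power *= th
    return float(num / denom)


@dataclass
class FuFsResult:
    Fs: float
    p: float
    s_prime: float  # Pr(K >= observed haplotype count | theta = k)
    k_obs: int
    theta_hat: float


def _fs_from_tail(tail: float) -> float:
    tail = min(max(tail, 1e-300), 1.0 - 1e-16)
    return math.log(tail / (1.0 - tail))


def fus_Fs(aln, seed: int = 0, n_replicates: int = 1000) -> FuFsResult:
    """Fu's Fs: log-odds of seeing at least the observed haplotype count
    under the Ewens expectation at θ = k (mean pairwise differences).

    S' is exact via Stirling numbers (rational arithmetic) for n ≤ 200,
    otherwise estimated from the sequential Ewens construction.  The
    p-value is the fraction of ``n_replicates`` neutral coalescent
    replicates simulated at θ = k whose Fs — recomputed on the replicate
    with its own estimated θ, exactly as on the data — is ≤ the observed
    Fs.  (The test is known to be anti-conservative at face value: its
    conventional 5%-level rejection uses p < 0.02.)
    """
    codes = aln.codes
    n = codes.shape[0]
    _, diff = _column_diff_pairs(codes)
    theta = float(diff.sum()) / (n * (n - 1) / 2.0)
    if theta <= 0:
        raise ValueError("k = 0: Fu's Fs undefined")
    complete = ~((codes == _N) | (codes == _GAP)).any(axis=0)
    k_obs = len({codes[i, complete].tobytes() for i in range(n)})
    rng = random.Random(seed)
    if n <= 200:
        s_prime = ewens_k_tail_probability(n, theta, k_obs)
    else:
        draws = [sample_ewens_k(n, theta, rng) for _ in range(100_000)]
        s_prime = sum(d >= k_obs for d in draws) / len(draws)
    if s_prime <= 0.0 or s_prime >= 1.0:
        warnings.warn("S' at machine boundary; clamping into (0,1)")
    fs = _fs_from_tail(s_prime)
    hits = 0
    for _ in range(n_replicates):
        k_rep, kh_rep = _neutral_K_khat(n, theta, rng)
        if kh_rep <= 0:
            continue  # Fs' = +inf: never as extreme as any finite observation
        if _fs_from_tail(_ewens_tail_float(n, kh_rep, k_rep)) <= fs:
            hits += 1
    return FuFsResult(fs, hits / n_replicates, s_prime, k_obs, theta)


# ---------------------------------------------------------------------------
# Hudson Fst


def _mean_pairwise_between(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Mean pairwise differences across all (a, b) pairs, pairwise deletion."""
    valid_a = np.isin(codes_a, _BASE_CODES)
    valid_b = np.isin(codes_b, _BASE_CODES)
    tot = 0.0
    for i in range(codes_a.shape[0]):
        both = valid_a[i] & valid_b
        tot += ((codes_a[i] != codes_b) & both).sum()
    return tot / (codes_a.shape[0] * codes_b.shape[0])


def _mean_pairwise_within(codes: np.ndarray) -> float:
    valid = np.isin(codes, _BASE_CODES)
    n = codes.shape[0]
    tot = 0.0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        tot += ((codes[i] != codes[i + 1 :]) & both).sum()
    return tot / (n * (n - 1) / 2.0)


def hudson_fst(aln, group_a, group_b, weighting: str = "equal") -> float | None:
    """Hudson's Fst = 1 − Hw/Hb between two sample groups.

    Hw is the mean of the within-group mean pairwise differences (equal
    group weight by default, ``weighting='size'`` for sample-size weights);
    Hb is the between-group mean.  Negative estimates are reported as
    computed.  Returns None when Hb = 0.
    """
    idx = {sid: i for i, sid in enumerate(aln.sample_ids)}
    ia = [idx[s] for s in group_a]
    ib = [idx[s] for s in group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need at least 2 samples")
    ca, cb = aln.codes[ia], aln.codes[ib]
    hw_a, hw_b = _mean_pairwise_within(ca), _mean_pairwise_within(cb)
    if weighting == "equal":
        hw = 0.5 * (hw_a + hw_b)
    elif weighting == "size":
        hw = (len(ia) * hw_a + len(ib) * hw_b) / (len(ia) + len(ib))
    else:
        raise ValueError("weighting must be 'equal' or 'size'")
    hb = _mean_pairwise_between(ca, cb)
    if hb == 0.0:
        return None
    return 1.0 - hw / hb
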