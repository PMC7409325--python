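"""Linkage disequilibrium, haplotype blocks, and recombination profiling.

Mitotypes are homoplasmic, so phase is known and every sample is one
haplotype.  After restricting to biallelic SNPs with minor-allele
frequency strictly above the configured threshold (default 10%), this
module computes:

* pairwise D, D' and r² with a 90% likelihood interval on D' (a grid scan
  of the multinomial haplotype likelihood, the classic block-calling
  ingredient);
* haplotype blocks under confidence-interval rules (strong LD: CI low
  ≥ 0.70 and high ≥ 0.98; strong recombination: CI high < 0.90; a block
  needs a strong-LD outermost pair and ≥95% strong-LD informative pairs
  inside);
* the Hudson–Kaplan minimum number of recombination events Rm
  (four-gamete incompatibilities → minimal interval cover);
* a relative recombination-intensity landscape: per adjacent-SNP
  interval, a windowed composite likelihood of local per-kb intensity —
  every nearby site pair crossing the interval contributes the likelihood
  of its two-locus haplotype configuration, read off a
  sampling-probability table precomputed once by two-locus coalescent
  simulation; intensities are reported relative to the genome-wide
  median.  (A single pair's configuration carries too little information
  to place it on a rho grid reliably; pooling the pairs that span the
  interval is what makes hotspot ranking stable.)
"""

from __future__ import annotations

import json
import math
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .popgen_stats import VariantTable

__all__ = [
    "LDPair",
    "HaplotypeBlock",
    "RecombinationInterval",
    "RecombinationProfile",
    "maf_filter",
    "pairwise_ld",
    "compute_ld_pairs",
    "gabriel_blocks",
    "hudson_kaplan_rm",
    "TwoLocusTable",
    "build_two_locus_table",
    "recombination_intensity",
    "interval_intensity",
    "RHO_GRID",
]

RHO_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass(frozen=True)
class LDPair:
    site_i: int
    site_j: int
    D: float
    D_prime: float
    r2: float
    ci_low: float
    ci_high: float
    n_informative: int


@dataclass(frozen=True)
class HaplotypeBlock:
    first_site: int
    last_site: int

    @property
    def n_sites(self) -> int:
        return self.last_site - self.first_site + 1


@dataclass(frozen=True)
class RecombinationInterval:
    left_site: int
    right_site: int
    left_pos: int
    right_pos: int
    rm_contribution: int
    rho_hat: float | None
    intensity: float | None


@dataclass
class RecombinationProfile:
    intervals: list[RecombinationInterval]
    rm_total: int
    rm_intervals: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# MAF filter


def maf_filter(variants: VariantTable, min_maf: float = 0.10) -> VariantTable:
    """Keep biallelic sites with minor-allele frequency strictly above
    ``min_maf``; multiallelic sites are first reduced to their two most
    frequent alleles (the rest become missing)."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    keep_cols, keep_alleles, geno_cols = [], [], []
    for s in range(variants.n_sites):
        g = variants.genotypes[:, s].copy()
        g[g > 1] = -1  # drop third and further alleles
        n0 = int((g == 0).sum())
        n1 = int((g == 1).sum())
        total = n0 + n1
        if total == 0 or min(n0, n1) == 0:
            continue
        if min(n0, n1) / total > min_maf:
            keep_cols.append(s)
            keep_alleles.append(variants.alleles[s][:2])
            geno_cols.append(g)
    genotypes = (
        np.stack(geno_cols, axis=1)
        if geno_cols
        else np.zeros((variants.n_samples, 0), np.int8)
    )
    return VariantTable(
        list(variants.sample_ids),
        variants.columns[keep_cols],
        keep_alleles,
        genotypes,
    )


# ---------------------------------------------------------------------------
# pairwise LD


def pairwise_ld(
    variants: VariantTable, site_i: int, site_j: int, grid_step: float = 0.001
) -> LDPair | None:
    """D, D' and r² for one biallelic site pair, with a 90% D' interval.

    Haplotype counts come from the samples non-missing at both sites; the
    interval is read from the normalized multinomial likelihood of |D'|
    on a 0.001 grid (cumulative 5% and 95% bounds).  Returns None when a
    site is monomorphic among the jointly non-missing samples.
    """
    gi = variants.genotypes[:, site_i]
    gj = variants.genotypes[:, site_j]
    both = (gi >= 0) & (gj >= 0)
    gi, gj = gi[both], gj[both]
    n = int(both.sum())
    n11 = int(((gi == 0) & (gj == 0)).sum())
    n10 = int(((gi == 0) & (gj == 1)).sum())
    n01 = int(((gi == 1) & (gj == 0)).sum())
    n00 = int(((gi == 1) & (gj == 1)).sum())
    pA = (n11 + n10) / n if n else 0.0
    pB = (n11 + n01) / n if n else 0.0
    if n == 0 or pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    pAB = n11 / n
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))

    dgrid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    dd = sign * dgrid * dmax
    p11 = np.clip(pA * pB + dd, 1e-12, 1.0)
    p10 = np.clip(pA * (1 - pB) - dd, 1e-12, 1.0)
    p01 = np.clip((1 - pA) * pB - dd, 1e-12, 1.0)
    p00 = np.clip((1 - pA) * (1 - pB) + dd, 1e-12, 1.0)
    ll = (
        n11 * np.log(p11) + n10 * np.log(p10) + n01 * np.log(p01) + n00 * np.log(p00)
    )
    w = np.exp(ll - ll.max())
    cum = np.cumsum(w) / w.sum()
    d_prime = min(d_prime, 1.0)
    # likelihood-interval bounds, widened to bracket the point estimate
    # (the 5% quantile of |D'| can sit above an ML estimate of exactly 0)
    ci_low = min(float(dgrid[np.searchsorted(cum, 0.05)]), d_prime)
    ci_high = max(
        float(dgrid[min(np.searchsorted(cum, 0.95), len(dgrid) - 1)]), d_prime
    )
    return LDPair(site_i, site_j, D, d_prime, min(r2, 1.0), ci_low, ci_high, n)


def compute_ld_pairs(variants: VariantTable) -> list[LDPair]:
    out = []
    for i in range(variants.n_sites):
        for j in range(i + 1, variants.n_sites):
            p = pairwise_ld(variants, i, j)
            if p is not None:
                out.append(p)
    return out


# ---------------------------------------------------------------------------
# haplotype blocks


def gabriel_blocks(pairs: list[LDPair], n_sites: int) -> list[HaplotypeBlock]:
    """Confidence-interval block calling over ordered sites.

    Pair classes — strong LD: ci_low ≥ 0.70 and ci_high ≥ 0.98; strong
    recombination: ci_high < 0.90; anything else uninformative.  A
    candidate [i..j] needs a strong-LD outermost pair and ≥95% strong-LD
    among its informative pairs; candidates are accepted greedily by
    decreasing span, discarding overlaps.
    """
    strong = {}
    informative = {}
    for p in pairs:
        is_strong = p.ci_low >= 0.70 and p.ci_high >= 0.98
        is_recomb = p.ci_high < 0.90
        if is_strong or is_recomb:
            informative[(p.site_i, p.site_j)] = True
            strong[(p.site_i, p.site_j)] = is_strong
    candidates = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if not strong.get((i, j), False):
                continue
            n_inf = n_str = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    if informative.get((a, b)):
                        n_inf += 1
                        if strong[(a, b)]:
                            n_str += 1
            if n_inf and n_str / n_inf >= 0.95:
                candidates.append((j - i, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    taken = np.zeros(n_sites, dtype=bool)
    blocks = []
    for _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(HaplotypeBlock(i, j))
    blocks.sort(key=lambda b: b.first_site)
    return blocks


# ---------------------------------------------------------------------------
# Hudson-Kaplan Rm


def _four_gamete_fail(variants: VariantTable, i: int, j: int) -> bool:
    gi = variants.genotypes[:, i]
    gj = variants.genotypes[:, j]
    both = (gi >= 0) & (gj >= 0)
    gi, gj = gi[both], gj[both]
    seen = {(int(a), int(b)) for a, b in zip(gi, gj)}
    return len(seen) == 4


def hudson_kaplan_rm(variants: VariantTable):
    """Minimum recombination events (Hudson–Kaplan bound).

    Every four-gamete-incompatible site pair defines an open interval that
    must contain at least one event; the greedy sort-by-right-endpoint
    scan yields a minimal set of disjoint intervals.  Returns
    ``(rm_total, chosen_intervals)`` with intervals as (left_site,
    right_site) index pairs.
    """
    incompatible = [
        (i, j)
        for i in range(variants.n_sites)
        for j in range(i + 1, variants.n_sites)
        if _four_gamete_fail(variants, i, j)
    ]
    incompatible.sort(key=lambda ij: (ij[1], ij[0]))
    chosen = []
    last_cut = -1
    for l, r in incompatible:
        if l >= last_cut:  # no cut strictly inside (l, r) yet
            last_cut = r
            chosen.append((l, r))
    return len(chosen), chosen


# ---------------------------------------------------------------------------
# two-locus sampling-probability table and intensity profile


def _canonical_config(n11: int, n10: int, n01: int, n00: int):
    c = (n11, n10, n01, n00)
    best = c
    for swap_loci in (False, True):
        a = (c[0], c[2], c[1], c[3]) if swap_loci else c
        for swap_a in (False, True):
            b = (a[2], a[3], a[0], a[1]) if swap_a else a
            for swap_b in (False, True):
                e = (b[1], b[0], b[3], b[2]) if swap_b else b
                if e < best:
                    best = e
    return best


def _two_locus_config(n: int, rho: float, rng: random.Random):
    """One two-locus coalescent replicate conditioned on one mutation per
    locus; returns the (n11, n10, n01, n00) haplotype configuration."""
    full = (1 << n) - 1
    lineages = [[1 << i, 1 << i, 0.0] for i in range(n)]
    rec_a: list[tuple[float, int]] = []
    rec_b: list[tuple[float, int]] = []
    t = 0.0
    while lineages:
        k = len(lineages)
        n_both = sum(1 for l in lineages if l[0] and l[1])
        coal = k * (k - 1) * 0.5
        rec = 0.5 * rho * n_both
        total = coal + rec
        t += rng.expovariate(total)
        if rng.random() * total < coal:
            i, j = rng.sample(range(k), 2)
            a, b = lineages[i], lineages[j]
            for lin in (a, b):
                if lin[0]:
                    rec_a.append((t - lin[2], lin[0]))
                if lin[1]:
                    rec_b.append((t - lin[2], lin[1]))
            ma, mb = a[0] | b[0], a[1] | b[1]
            if ma == full:
                ma = 0
            if mb == full:
                mb = 0
            for idx in sorted((i, j), reverse=True):
                lineages.pop(idx)
            if ma or mb:
                lineages.append([ma, mb, t])
        else:
            cands = [idx for idx, l in enumerate(lineages) if l[0] and l[1]]
            idx = cands[rng.randrange(len(cands))]
            lin = lineages.pop(idx)
            rec_a.append((t - lin[2], lin[0]))
            rec_b.append((t - lin[2], lin[1]))
            lineages.append([lin[0], 0, t])
            lineages.append([0, lin[1], t])

    def draw(records):
        wt = sum(w for w, _ in records)
        u = rng.random() * wt
        for w, mask in records:
            if u < w:
                return mask
            u -= w
        return records[-1][1]

    ma, mb = draw(rec_a), draw(rec_b)
    n11 = (ma & mb).bit_count()
    n10 = (ma & ~mb).bit_count()
    n01 = (mb & ~ma).bit_count()
    return n11, n10, n01, n - n11 - n10 - n01


class TwoLocusTable:
    """Sampling probabilities of two-locus haplotype configurations, by rho.

    Built once by coalescent simulation (conditioned on each locus being
    segregating), keyed by canonical configuration — canonical over allele
    relabelling at either locus and locus exchange.  Lookups use add-half
    smoothing over the configuration classes.
    """

    def __init__(self, n: int, rho_grid, counts: dict, reps: int):
        self.n = n
        self.rho_grid = tuple(float(r) for r in rho_grid)
        self.counts = counts  # {rho: {canonical-config: count}}
        self.reps = reps
        self._n_classes = self._count_classes(n)

    @staticmethod
    def _count_classes(n: int) -> int:
        classes = set()
        for n11 in range(n + 1):
            for n10 in range(n + 1 - n11):
                for n01 in range(n + 1 - n11 - n10):
                    n00 = n - n11 - n10 - n01
                    if 0 < n11 + n10 < n and 0 < n11 + n01 < n:
                        classes.add(_canonical_config(n11, n10, n01, n00))
        return len(classes)

    def log_likelihood(self, config, rho: float) -> float:
        key = _canonical_config(*config)
        c = self.counts[rho].get(key, 0)
        return math.log((c + 0.5) / (self.reps + 0.5 * self._n_classes))

    def best_rho(self, config) -> float:
        best, best_ll = None, None
        for rho in self.rho_grid:
            ll = self.log_likelihood(config, rho)
            if best_ll is None or ll > best_ll + 1e-12:
                best, best_ll = rho, ll
        return best

    def save(self, path) -> None:
        payload = {
            "n": self.n,
            "reps": self.reps,
            "rho_grid": list(self.rho_grid),
            "counts": {
                repr(rho): {",".join(map(str, k)): v for k, v in tab.items()}
                for rho, tab in self.counts.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "TwoLocusTable":
        payload = json.loads(Path(path).read_text())
        counts = {
            float(rho): {
                tuple(map(int, k.split(","))): v for k, v in tab.items()
            }
            for rho, tab in payload["counts"].items()
        }
        return cls(payload["n"], payload["rho_grid"], counts, payload["reps"])


def build_two_locus_table(
    n: int = 20,
    rho_grid=RHO_GRID,
    reps: int = 20000,
    seed: int = 0,
) -> TwoLocusTable:
    """Simulate the two-locus configuration table (one rng per grid point,
    derived from ``seed``, so the table is reproducible)."""
    counts: dict[float, Counter] = {}
    for gi, rho in enumerate(rho_grid):
        rng = random.Random((seed * 1009 + gi * 101 + 1) % (2**31))
        tab: Counter = Counter()
        for _ in range(reps):
            tab[_two_locus_config(n, rho, rng)] += 1
        counts[float(rho)] = tab
    return TwoLocusTable(n, rho_grid, counts, reps)


def _nearest_grid_rho(x: float, grid=RHO_GRID) -> float:
    """Round a rho value onto the table grid (geometric rounding; values
    at or below the 0/0.5 midpoint map to 0)."""
    if x <= 0.25:
        return 0.0
    return min(grid[1:], key=lambda g: abs(math.log(x) - math.log(g)))


def recombination_intensity(
    variants: VariantTable,
    table: TwoLocusTable,
    seed: int = 0,
    max_span_sites: int = 14,
    max_span_bp: int = 1000,
    n_subsample_draws: int = 5,
    intensity_grid=RHO_GRID,
) -> RecombinationProfile:
    """Relative recombination landscape over adjacent SNP intervals.

    For each adjacent-site interval, the local per-kb recombination
    intensity is estimated by composite likelihood: every site pair within
    ``max_span_sites`` sites and ``max_span_bp`` bp that crosses the
    interval contributes the table likelihood of its haplotype
    configuration, evaluated at a candidate per-kb intensity scaled by the
    pair's physical distance (rounded onto the table's rho grid).  The
    per-interval estimate is the argmax over ``intensity_grid`` (in rho
    per kb; ties to the smaller value), and λ is that estimate divided by
    the genome-wide median (reported unnormalized when the median is 0).
    Configurations are subsampled to the table's n; several seeded draws
    are averaged to damp subsampling noise.  The Hudson–Kaplan cut count
    per interval rides along as the event-bound contribution.
    """
    rng = random.Random(seed)
    rm_total, rm_cuts = hudson_kaplan_rm(variants)
    cuts_per_gap = Counter()
    for l, r in rm_cuts:
        cuts_per_gap[r - 1] += 1  # greedy places the event in the gap (r-1, r)

    pos = variants.columns
    S = variants.n_sites
    config_cache: dict[tuple[int, int], list] = {}

    def pair_configs(a: int, b: int) -> list:
        if (a, b) in config_cache:
            return config_cache[(a, b)]
        gi = variants.genotypes[:, a]
        gj = variants.genotypes[:, b]
        both = list(map(int, np.nonzero((gi >= 0) & (gj >= 0))[0]))
        out = []
        if len(both) >= table.n:
            for _ in range(n_subsample_draws):
                sub = rng.sample(both, table.n)
                x, y = gi[sub], gj[sub]
                n11 = int(((x == 1) & (y == 1)).sum())
                n10 = int(((x == 1) & (y == 0)).sum())
                n01 = int(((x == 0) & (y == 1)).sum())
                cfg = (n11, n10, n01, table.n - n11 - n10 - n01)
                if cfg[0] + cfg[1] not in (0, table.n) and cfg[0] + cfg[2] not in (
                    0,
                    table.n,
                ):
                    out.append(cfg)
        config_cache[(a, b)] = out
        return out

    rho_hats: list[float | None] = []
    for i in range(S - 1):
        lls = np.zeros(len(intensity_grid))
        n_pairs = 0
        for a in range(max(0, i - max_span_sites + 1), i + 1):
            for b in range(i + 1, min(S, i + 1 + max_span_sites)):
                if b - a > max_span_sites or pos[b] - pos[a] > max_span_bp:
                    continue
                cfgs = pair_configs(a, b)
                if not cfgs:
                    continue
                d_kb = (pos[b] - pos[a]) / 1000.0
                n_pairs += 1
                for k, c in enumerate(intensity_grid):
                    r = _nearest_grid_rho(c * d_kb, table.rho_grid)
                    lls[k] += sum(table.log_likelihood(cfg, r) for cfg in cfgs) / len(
                        cfgs
                    )
        rho_hats.append(
            float(intensity_grid[int(np.argmax(lls))]) if n_pairs else None
        )

    defined = [r for r in rho_hats if r is not None]
    med = float(np.median(defined)) if defined else 0.0
    norm = med if med > 0 else 1.0
    intervals = []
    for s, rho_hat in enumerate(rho_hats):
        intervals.append(
            RecombinationInterval(
                left_site=s,
                right_site=s + 1,
                left_pos=int(variants.columns[s]),
                right_pos=int(variants.columns[s + 1]),
                rm_contribution=int(cuts_per_gap.get(s, 0)),
                rho_hat=rho_hat,
                intensity=None if rho_hat is None else rho_hat / norm,
            )
        )
    return RecombinationProfile(intervals, rm_total, rm_cuts)


def interval_intensity(
    profile: RecombinationProfile, interval: tuple[int, int]
) -> float | None:
    """Peak λ among profile intervals overlapping a physical interval
    (e.g. one intergenic spacer) — the landscape readout for ranking
    candidate hotspot regions."""
    a, b = interval
    vals = [
        iv.intensity
        for iv in profile.intervals
        if iv.intensity is not None and iv.right_pos > a and iv.left_pos < b
    ]
    return max(vals) if vals else None
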