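"""Structured coalescent with recombination (Hudson-style ARG).

This is the sampling engine behind the synthetic mitogenome populations:
an ancestral recombination graph over the unit interval, with

* a symmetric island model (``d`` demes, per-lineage migration rate ``m``,
  time scaled so one within-deme pair coalesces at rate 1),
* a piecewise-constant recombination intensity map (the population
  parameter rho integrates the map over [0, 1)), so recombination can be
  concentrated in chosen intervals (hotspots between genes),
* infinite-sites mutations laid on the realized branches at rate theta/2
  per unit of ancestral material per unit time.

Each lineage carries its ancestral material as a list of segments, each
segment annotated with the frozen set of sample indices that descend from
it.  A segment whose descendant set reaches the full sample has found its
marginal MRCA and is dropped, so the simulation stops exactly when every
position has coalesced.  Every recombination event is logged with its
breakpoint position, which downstream tests use as the realized-event
truth (e.g. to check that the Hudson–Kaplan Rm bound is a lower bound).
"""

from __future__ import annotations

import bisect
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "RateMap",
    "uniform_rate_map",
    "Mutation",
    "ARG",
    "simulate_arg",
    "drop_mutations",
    "drop_fixed_mutations",
    "ewens_allele_counts",
    "sample_ewens_k",
]


# ---------------------------------------------------------------------------
# recombination rate map


class RateMap:
    """Piecewise-constant recombination intensity over [0, 1).

    ``breaks`` are the interval boundaries (first 0.0, last 1.0) and
    ``rates`` the population recombination intensity (rho per unit length)
    on each interval; ``total(a, b)`` integrates the map.
    """

    def __init__(self, breaks: Sequence[float], rates: Sequence[float]):
        if len(breaks) != len(rates) + 1:
            raise ValueError("need len(breaks) == len(rates) + 1")
        if breaks[0] != 0.0 or breaks[-1] != 1.0:
            raise ValueError("rate map must span [0, 1]")
        if any(b >= c for b, c in zip(breaks, breaks[1:])):
            raise ValueError("breaks must be strictly increasing")
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        self.breaks = list(map(float, breaks))
        self.rates = list(map(float, rates))
        # cumulative integral at each break
        self._cum = [0.0]
        for (b0, b1), r in zip(zip(self.breaks, self.breaks[1:]), self.rates):
            self._cum.append(self._cum[-1] + (b1 - b0) * r)

    @property
    def total_rate(self) -> float:
        return self._cum[-1]

    def cumulative(self, x: float) -> float:
        """Integral of the intensity over [0, x)."""
        if x <= 0.0:
            return 0.0
        if x >= 1.0:
            return self._cum[-1]
        i = bisect.bisect_right(self.breaks, x) - 1
        return self._cum[i] + (x - self.breaks[i]) * self.rates[i]

    def total(self, a: float, b: float) -> float:
        return self.cumulative(b) - self.cumulative(a)

    def inverse_cumulative(self, c: float) -> float:
        """Position x with cumulative(x) == c (c in (0, total_rate))."""
        i = bisect.bisect_right(self._cum, c) - 1
        i = min(i, len(self.rates) - 1)
        r = self.rates[i]
        if r <= 0.0:
            return self.breaks[i + 1]
        return self.breaks[i] + (c - self._cum[i]) / r


def uniform_rate_map(rho: float) -> RateMap:
    """Uniform map with total population recombination parameter ``rho``."""
    return RateMap([0.0, 1.0], [rho])


# ---------------------------------------------------------------------------
# ARG machinery

# a segment is (left, right, samples-frozenset); lineages keep them sorted


@dataclass
class _Lineage:
    segments: list
    deme: int
    record_index: int  # open branch record

    def span(self):
        return self.segments[0][0], self.segments[-1][1]

    def material(self) -> float:
        return sum(r - l for l, r, _ in self.segments)


@dataclass
class Mutation:
    position: float
    carriers: frozenset


@dataclass
class ARG:
    """Realized ancestry: branch records plus the recombination event log.

    ``branch_records`` is a list of ``(t0, t1, segments)`` — a lineage that
    existed from ``t0`` to ``t1`` carrying ``segments`` (each with its
    descendant sample set).  Mutations are laid on these records.
    """

    n: int
    branch_records: list = field(default_factory=list)
    recombination_events: list = field(default_factory=list)  # (time, position)

    @property
    def total_branch_material(self) -> float:
        return sum(
            (t1 - t0) * sum(r - l for l, r, _ in segs)
            for t0, t1, segs in self.branch_records
        )


def _merge_segments(a: list, b: list, full: frozenset):
    """Union two segment lists; drop stretches that reach the full sample."""
    points = sorted({p for l, r, _ in a + b for p in (l, r)})
    out = []
    ia = ib = 0
    for left, right in zip(points, points[1:]):
        mid = 0.5 * (left + right)
        s: frozenset | None = None
        while ia < len(a) and a[ia][1] <= left:
            ia += 1
        if ia < len(a) and a[ia][0] <= mid < a[ia][1]:
            s = a[ia][2]
        while ib < len(b) and b[ib][1] <= left:
            ib += 1
        if ib < len(b) and b[ib][0] <= mid < b[ib][1]:
            s = b[ib][2] if s is None else (s | b[ib][2])
        if s is None or s == full:
            continue
        if out and out[-1][1] == left and out[-1][2] == s:
            out[-1] = (out[-1][0], right, s)
        else:
            out.append((left, right, s))
    return out


def simulate_arg(
    n_per_deme: Sequence[int],
    migration: float = 0.0,
    rate_map: RateMap | None = None,
    rng: random.Random | None = None,
) -> ARG:
    """Run the structured coalescent with recombination to the grand MRCA.

    Parameters
    ----------
    n_per_deme:
        Sample sizes, one entry per deme.  Total sample size is capped at
        100 (the generator is desk-scale by design).
    migration:
        Per-lineage migration rate (symmetric island model); ignored with
        a single deme.
    rate_map:
        Recombination intensity map; default no recombination.
    rng:
        ``random.Random`` driving every draw; required for reproducibility.
    """
    if rng is None:
        raise ValueError("an explicit random.Random is required")
    n_total = int(sum(n_per_deme))
    if n_total > 100:
        raise ValueError("total sample size capped at 100")
    if n_total < 2:
        raise ValueError("need at least 2 samples")
    n_demes = len(n_per_deme)
    if n_demes > 1 and migration <= 0.0:
        raise ValueError("multiple demes require a positive migration rate")
    rate_map = rate_map if rate_map is not None else uniform_rate_map(0.0)

    full = frozenset(range(n_total))
    arg = ARG(n=n_total)
    lineages: list[_Lineage] = []
    t = 0.0
    sample = 0
    for deme, k in enumerate(n_per_deme):
        for _ in range(k):
            segs = [(0.0, 1.0, frozenset([sample]))]
            arg.branch_records.append([t, None, segs])
            lineages.append(_Lineage(segs, deme, len(arg.branch_records) - 1))
            sample += 1

    def close(lin: _Lineage, time: float):
        arg.branch_records[lin.record_index][1] = time

    def open_lineage(segs: list, deme: int, time: float) -> _Lineage:
        arg.branch_records.append([time, None, segs])
        return _Lineage(segs, deme, len(arg.branch_records) - 1)

    while lineages:
        by_deme: dict[int, list[int]] = {}
        for i, lin in enumerate(lineages):
            by_deme.setdefault(lin.deme, []).append(i)
        coal_rate = sum(len(v) * (len(v) - 1) / 2.0 for v in by_deme.values())
        rec_rates = [
            0.5 * rate_map.total(*lin.span()) for lin in lineages
        ]
        rec_rate = sum(rec_rates)
        mig_rate = migration * len(lineages) if n_demes > 1 else 0.0
        total = coal_rate + rec_rate + mig_rate
        if total <= 0.0:
            # isolated lineages in separate demes with no migration cannot
            # happen (migration required above); only reachable if a single
            # lineage remains with no recombination material — done.
            break
        t += rng.expovariate(total)
        u = rng.random() * total
        if u < coal_rate:
            # coalescence: pick a deme weighted by its pair count, then a pair
            target = u
            for deme, idxs in by_deme.items():
                w = len(idxs) * (len(idxs) - 1) / 2.0
                if target < w:
                    i, j = rng.sample(idxs, 2)
                    break
                target -= w
            a, b = lineages[i], lineages[j]
            close(a, t)
            close(b, t)
            merged = _merge_segments(a.segments, b.segments, full)
            for k in sorted((i, j), reverse=True):
                lineages.pop(k)
            if merged:
                lineages.append(open_lineage(merged, a.deme, t))
        elif u < coal_rate + rec_rate:
            target = u - coal_rate
            for i, w in enumerate(rec_rates):
                if target < w:
                    break
                target -= w
            lin = lineages[i]
            lo, hi = lin.span()
            c = rate_map.cumulative(lo) + rng.random() * rate_map.total(lo, hi)
            pos = rate_map.inverse_cumulative(c)
            left = [s for s in lin.segments if s[0] < pos]
            right = [s for s in lin.segments if s[1] > pos]
            left = [(l, min(r, pos), s) for l, r, s in left]
            right = [(max(l, pos), r, s) for l, r, s in right]
            left = [s for s in left if s[1] > s[0]]
            right = [s for s in right if s[1] > s[0]]
            if not left or not right:
                continue  # breakpoint outside effective material; no event
            arg.recombination_events.append((t, pos))
            close(lin, t)
            lineages.pop(i)
            lineages.append(open_lineage(left, lin.deme, t))
            lineages.append(open_lineage(right, lin.deme, t))
        else:
            i = rng.randrange(len(lineages))
            lin = lineages[i]
            new_deme = rng.randrange(n_demes - 1)
            if new_deme >= lin.deme:
                new_deme += 1
            # deme change does not alter material; keep the record open
            lin.deme = new_deme

    # close any straggler records (single lineage left with material cannot
    # occur: material without full descendant set implies >1 lineage)
    for rec in arg.branch_records:
        if rec[1] is None:
            rec[1] = t
    arg.branch_records = [
        (t0, t1, segs) for t0, t1, segs in arg.branch_records if t1 > t0 and segs
    ]
    return arg


def _record_weights(arg: ARG) -> list[float]:
    return [
        (t1 - t0) * sum(r - l for l, r, _ in segs)
        for t0, t1, segs in arg.branch_records
    ]


def _position_in(segs: list, u: float) -> tuple[float, frozenset]:
    """Map u in [0, material) onto a position within the segments."""
    for l, r, s in segs:
        w = r - l
        if u < w:
            return l + u, s
        u -= w
    l, r, s = segs[-1]
    return r - 1e-12, s


def drop_mutations(arg: ARG, theta: float, rng: random.Random) -> list[Mutation]:
    """Poisson infinite-sites mutations at rate theta/2 per unit material-time."""
    weights = _record_weights(arg)
    w_total = sum(weights)
    n_mut = _poisson(0.5 * theta * w_total, rng)
    return _place(arg, weights, w_total, n_mut, rng)


def drop_fixed_mutations(arg: ARG, s: int, rng: random.Random) -> list[Mutation]:
    """Place exactly ``s`` mutations, multinomially by branch material-time."""
    weights = _record_weights(arg)
    return _place(arg, weights, sum(weights), s, rng)


def _place(arg, weights, w_total, n_mut, rng) -> list[Mutation]:
    if n_mut == 0 or w_total <= 0:
        return []
    cum = []
    acc = 0.0
    for w in weights:
        acc += w
        cum.append(acc)
    muts = []
    for _ in range(n_mut):
        u = rng.random() * w_total
        i = bisect.bisect_right(cum, u)
        i = min(i, len(weights) - 1)
        t0, t1, segs = arg.branch_records[i]
        v = rng.random() * sum(r - l for l, r, _ in segs)
        pos, carriers = _position_in(segs, v)
        muts.append(Mutation(pos, carriers))
    muts.sort(key=lambda m: m.position)
    return muts


def _poisson(lam: float, rng: random.Random) -> int:
    if lam <= 0:
        return 0
    if lam > 700:  # normal approximation far beyond any desk-scale use
        return max(0, int(round(rng.gauss(lam, math.sqrt(lam)))))
    l = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= l:
            return k
        k += 1


# ---------------------------------------------------------------------------
# Ewens sampling formula helpers (Fu's Fs machinery and its null replicates)


def sample_ewens_k(n: int, theta: float, rng: random.Random) -> int:
    """Number of distinct alleles under the Ewens sampling formula.

    Sequential construction: the i-th sequence founds a new allele with
    probability theta / (theta + i - 1), independently — exactly the
    haplotype-count law of the neutral infinite-sites coalescent without
    recombination.
    """
    k = 0
    for i in range(n):
        if rng.random() < theta / (theta + i):
            k += 1
    return k


def ewens_allele_counts(n: int, theta: float, rng: random.Random) -> list[int]:
    """Full allele configuration via the Chinese-restaurant construction."""
    counts: list[int] = []
    for i in range(n):
        if rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            u = rng.random() * i
            acc = 0.0
            for j, c in enumerate(counts):
                acc += c
                if u < acc:
                    counts[j] += 1
                    break
    return counts
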