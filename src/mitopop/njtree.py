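"""Neighbor joining (Saitou–Nei, Studier–Keppler Q-criterion).

NJ is the workhorse clustering method for recombining data where true
phylogenies are not meaningful: it is exact on additive distance matrices
and otherwise produces a useful distance-based grouping.  Ties on the
Q-criterion are broken deterministically by the smallest (row, col) index
pair in the current node ordering; negative branch lengths are clamped to
zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NJTree", "neighbor_joining"]


@dataclass
class NJTree:
    """Unrooted tree: leaves 0..n-1 labelled by ``taxa``, internal nodes above."""

    taxa: list[str]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def adjacency(self):
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        return adj

    def newick(self) -> str:
        adj = self.adjacency()
        root = max(adj)  # final internal node; renders unrooted as basal split

        def render(node, parent):
            kids = [(v, w) for v, w in adj[node] if v != parent]
            if not kids:
                return self.taxa[node]
            inner = ",".join(
                f"{render(v, node)}:{w:.10g}" for v, w in kids
            )
            return f"({inner})"

        return render(root, None) + ";"

    def leaf_distances(self) -> np.ndarray:
        """Path-length distances between all leaf pairs."""
        adj = self.adjacency()
        n = len(self.taxa)
        out = np.zeros((n, n))
        for start in range(n):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for leaf in range(n):
                out[start, leaf] = dist[leaf]
        return out


def neighbor_joining(dist: np.ndarray, taxa: list[str] | None = None) -> NJTree:
    """Build an unrooted NJ tree from a symmetric zero-diagonal matrix."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = list(taxa) if taxa is not None else [f"t{i}" for i in range(n)]

    tree = NJTree(taxa)
    active = list(range(n))  # node ids, in creation order
    D = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_node = n
    clamped = False

    def get(i, j):
        return D[(i, j) if i < j else (j, i)]

    def attach(u, v, w):
        nonlocal clamped
        if w < 0:
            clamped = True
            w = 0.0
        tree.edges.append((u, v, w))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for a in range(m):
            for b in range(a + 1, m):
                i, j = active[a], active[b]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best:
                    best = q
                    best_pair = (a, b)
        a, b = best_pair
        i, j = active[a], active[b]
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        attach(i, u, li)
        attach(j, u, lj)
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, u), max(k, u))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    # resolve the final three nodes around a hub with the three-point formulas
    i, j, k = active
    u = next_node
    attach(i, u, 0.5 * (get(i, j) + get(i, k) - get(j, k)))
    attach(j, u, 0.5 * (get(i, j) + get(j, k) - get(i, k)))
    attach(k, u, 0.5 * (get(i, k) + get(j, k) - get(i, j)))
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return tree
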