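"""Reference-anchored alignment, missingness filtering, and imputation.

Core sequences are aligned sample-by-sample against the core reference,
region by region, and projected onto reference columns: every matrix
column corresponds to one core-reference position, sample insertions are
dropped (counted in a side report), and deletions appear as ``-``.  This
replaces a progressive multiple alignment — coding regions are conserved
and the reference coordinate system is what every downstream statistic
needs.

Missingness semantics: ``N`` (unread) is missing; ``-`` is an observed
deletion and is NOT missing.  Samples with missing fraction strictly
greater than the threshold (default 10%) are dropped.  Remaining ``N``s
are imputed from the closest relatives on an NJ guide tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_reference import CoreReferenceSet, CoreSequence
from .njtree import neighbor_joining

__all__ = [
    "AlignmentMatrix",
    "MissingnessReport",
    "anchor_align",
    "filter_missing_samples",
    "impute_positions",
]

_N = ord("N")
_GAP = ord("-")
_BASES = frozenset(b"ACGT")


@dataclass
class AlignmentMatrix:
    """samples × core-columns character matrix over {A,C,G,T,N,-}.

    ``codes`` holds ASCII byte values; ``column_map`` gives the
    core-reference coordinate of every column.
    """

    sample_ids: list[str]
    codes: np.ndarray
    column_map: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.column_map = np.asarray(self.column_map, dtype=int)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.sample_ids):
            raise ValueError("codes must be samples x columns")
        if self.codes.shape[1] != len(self.column_map):
            raise ValueError("column_map length mismatch")
        if len(self.column_map) > 1 and not np.all(np.diff(self.column_map) > 0):
            raise ValueError("column_map must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def row_string(self, i: int) -> str:
        return self.codes[i].tobytes().decode()

    @classmethod
    def from_strings(cls, sample_ids, rows, column_map=None):
        codes = np.array([list(r.encode()) for r in rows], dtype=np.uint8)
        if column_map is None:
            column_map = np.arange(codes.shape[1])
        return cls(list(sample_ids), codes, column_map)

    def missing_fraction(self) -> np.ndarray:
        return (self.codes == _N).mean(axis=1)

    def subset(self, keep_idx) -> "AlignmentMatrix":
        keep_idx = list(keep_idx)
        return AlignmentMatrix(
            [self.sample_ids[i] for i in keep_idx],
            self.codes[keep_idx].copy(),
            self.column_map.copy(),
        )


@dataclass
class MissingnessReport:
    missing_fraction: dict[str, float]
    dropped_samples: list[str]
    threshold: float


_GLOBAL_ALIGNER = None


def _global_aligner():
    """Affine global aligner for anchoring: match +1, mismatch −1,
    open −4, extend −1; N neutral."""
    global _GLOBAL_ALIGNER
    if _GLOBAL_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        m = substitution_matrices.Array("ACGTN", dims=2)
        for a in "ACGTN":
            for b in "ACGTN":
                m[a, b] = 0.0 if "N" in (a, b) else (1.0 if a == b else -1.0)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = m
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -1.0
        _GLOBAL_ALIGNER = aligner
    return _GLOBAL_ALIGNER


def _project(ref: str, sample: str):
    """Globally align ``sample`` to ``ref`` and project onto ref columns.

    Returns (row string over ref columns, inserted-base count, identity
    over ref columns).
    """
    if sample == ref:
        return sample, 0, 1.0
    if set(sample) <= {"N"}:
        return "N" * len(ref), 0, 0.0
    aln = _global_aligner().align(ref, sample)[0]
    ref_blocks, smp_blocks = aln.aligned
    row = ["-"] * len(ref)
    inserted = len(sample)
    for (r0, r1), (s0, s1) in zip(ref_blocks, smp_blocks):
        row[r0:r1] = sample[s0:s1]
        inserted -= s1 - s0
    row = "".join(row)
    informative = [(a, b) for a, b in zip(ref, row) if a != "N" and b != "N"]
    identity = (
        sum(a == b for a, b in informative) / len(informative) if informative else 0.0
    )
    return row, inserted, identity


def anchor_align(
    core: CoreReferenceSet,
    core_seqs: list[CoreSequence],
    min_identity: float = 0.5,
):
    """Align every sample's core material to the core reference.

    Returns ``(AlignmentMatrix, insertion_counts, excluded_samples)``.
    Samples aligning below ``min_identity`` over the whole core are
    excluded with a warning.
    """
    rows, ids = [], []
    insertions: dict[str, int] = {}
    excluded: list[str] = []
    region_seqs = [core.region_sequence(i) for i in range(len(core.regions))]
    for cs in core_seqs:
        parts, ins, n_match, n_inf = [], 0, 0, 0
        for ref, seq in zip(region_seqs, cs.region_seqs):
            row, k, _ = _project(ref, seq)
            parts.append(row)
            ins += k
        row = "".join(parts)
        # identity over non-N columns; gaps count against (a gap-riddled
        # alignment of unrelated sequence must not look "identical")
        inf = [
            (a, b)
            for a, b in zip(core.concatenated_sequence, row)
            if a != "N" and b != "N"
        ]
        identity = sum(a == b for a, b in inf) / len(inf) if inf else 0.0
        if inf and identity < min_identity:
            warnings.warn(
                f"sample {cs.genome_id} aligns at {identity:.2f} identity; excluded"
            )
            excluded.append(cs.genome_id)
            continue
        rows.append(row)
        ids.append(cs.genome_id)
        insertions[cs.genome_id] = ins
    aln = AlignmentMatrix.from_strings(ids, rows, np.arange(core.total_length))
    return aln, insertions, excluded


def filter_missing_samples(
    aln: AlignmentMatrix, threshold: float = 0.10
) -> tuple[AlignmentMatrix, MissingnessReport]:
    """Drop samples whose unread (N) fraction strictly exceeds ``threshold``.

    Exactly-at-threshold samples are retained ("more than 10%" is a strict
    inequality); gaps are observed deletions and never count as missing.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0,1]")
    frac = aln.missing_fraction()
    keep = [i for i, f in enumerate(frac) if f <= threshold]
    dropped = [aln.sample_ids[i] for i, f in enumerate(frac) if f > threshold]
    if not keep:
        raise ValueError("all samples dropped by the missingness filter")
    report = MissingnessReport(
        {sid: float(f) for sid, f in zip(aln.sample_ids, frac)}, dropped, threshold
    )
    return aln.subset(keep), report


def _p_distance_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of N (gaps compare as
    characters: a shared deletion is similarity, a gap/base mismatch counts)."""
    n = codes.shape[0]
    valid = codes != _N
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & both
        nb = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(nb > 0, diff.sum(axis=1) / np.maximum(nb, 1), 0.0)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def impute_positions(
    aln: AlignmentMatrix,
    seed: int = 0,
    n_neighbors: int = 5,
    min_informative: int = 3,
) -> AlignmentMatrix:
    """Impute unread positions from the nearest leaves of an NJ guide tree.

    For every ``N``, the closest ``n_neighbors`` samples (tree path
    length) that are non-N at that column vote; a strict majority base is
    imputed, ties or fewer than ``min_informative`` voters leave the N in
    place.  Deterministic: neighbor ranking ties break by sample order.
    """
    codes = aln.codes.copy()
    n = aln.n_samples
    if n < 3 or not (codes == _N).any():
        return AlignmentMatrix(list(aln.sample_ids), codes, aln.column_map.copy())
    dmat = _p_distance_matrix(codes)
    tree = neighbor_joining(dmat, aln.sample_ids)
    tdist = tree.leaf_distances()
    # stable neighbor order per sample: by (distance, index), self excluded
    tdist_self = tdist.copy()
    np.fill_diagonal(tdist_self, np.inf)
    order = np.argsort(tdist_self, axis=1, kind="stable")
    for i, c in zip(*np.nonzero(codes == _N)):
        votes: dict[int, int] = {}
        found = 0
        for j in order[i]:
            b = codes[j, c]
            if b == _N:
                continue
            votes[b] = votes.get(b, 0) + 1
            found += 1
            if found == n_neighbors:
                break
        if found < min_informative:
            continue
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # tie: leave unread
        if ranked[0][0] == _GAP:
            continue  # never impute a deletion as if it were a base call
        codes[i, c] = ranked[0][0]
    return AlignmentMatrix(list(aln.sample_ids), codes, aln.column_map.copy())
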