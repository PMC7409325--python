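"""Construction of the comparable core reference.

Yeast mitogenomes cannot be multiple-aligned whole: intergenic spacers are
nearly pure AT, highly repetitive and wildly variable in length, and gene
content differs between strains.  The workaround implemented here is to
restrict analysis to the protein-coding regions present in *every* genome
of a panel, concatenated in reference order into a single "core" sequence
that serves as a common coordinate system.

A gene counts as present in a genome if it is annotated there, or if a
similarity search (:func:`locate_region`, a seed-and-extend local aligner)
finds it — this rescues genes that are present in the DNA but missing from
a sparse annotation.  Genes whose sequence is genuinely absent from any
genome are excluded from the core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneFeature",
    "AnnotatedMitogenome",
    "CoreRegion",
    "CoreReferenceSet",
    "RegionHit",
    "CoreSequence",
    "reverse_complement",
    "locate_region",
    "shared_gene_set",
    "build_core_reference",
    "extract_core_sequence",
    "local_align",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A coding feature; coordinates 0-based half-open on the linearized genome.

    ``wrap`` marks a feature spanning the circular origin: its sequence is
    ``seq[start:] + seq[:end]``.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    wrap: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not self.wrap and not (0 <= self.start < self.end):
            raise ValueError(f"bad feature coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        # wrap length needs the genome length; computed in extract
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    genome_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self):
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.genome_id}: non-ACGTN symbols {bad}")
        for f in self.features:
            if not f.wrap and f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.name} exceeds genome {self.genome_id} length"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_names(self) -> list[str]:
        return [f.name for f in self.features]

    def find_gene(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def feature_sequence(self, f: GeneFeature) -> str:
        """Coding-strand sequence of a feature (wrap-aware)."""
        if f.wrap:
            raw = self.sequence[f.start:] + self.sequence[: f.end]
        else:
            raw = self.sequence[f.start : f.end]
        return reverse_complement(raw) if f.strand == "-" else raw


@dataclass(frozen=True)
class CoreRegion:
    gene_name: str
    ref_start: int  # 0-based on the reference genome
    length: int
    strand: str

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("region length must be positive")


@dataclass
class CoreReferenceSet:
    reference_id: str
    regions: list[CoreRegion]
    concatenated_sequence: str

    def __post_init__(self):
        if self.total_length != len(self.concatenated_sequence):
            raise ValueError("concatenated sequence length mismatch")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regions)

    def region_slices(self) -> list[tuple[int, int]]:
        """Half-open slices of each region within the concatenation."""
        out, off = [], 0
        for r in self.regions:
            out.append((off, off + r.length))
            off += r.length
        return out

    def region_sequence(self, i: int) -> str:
        a, b = self.region_slices()[i]
        return self.concatenated_sequence[a:b]


@dataclass(frozen=True)
class RegionHit:
    genome_id: str
    gene_name: str
    start: int
    end: int
    strand: str
    identity_fraction: float
    coverage_fraction: float

    def __post_init__(self):
        if not (0 <= self.identity_fraction <= 1 and 0 <= self.coverage_fraction <= 1):
            raise ValueError("identity/coverage must lie in [0,1]")
        if self.end <= self.start:
            raise ValueError("hit end must exceed start")


@dataclass
class CoreSequence:
    """Per-sample core material: one sequence per core region, with provenance
    ('annotated' | 'rescued' | 'missing') and the rescue hit when applicable."""

    genome_id: str
    region_seqs: list[str]
    provenance: list[str]
    hits: list[RegionHit | None]

    def concatenated(self) -> str:
        return "".join(self.region_seqs)


# ---------------------------------------------------------------------------
# seed-and-extend local search

_LOCAL_ALIGNER = None


def _local_aligner():
    """Affine-gap local aligner: match +1, mismatch −1, open −2, extend −1;
    N is neutral (scores 0 against everything)."""
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        m = substitution_matrices.Array("ACGTN", dims=2)
        for a in "ACGTN":
            for b in "ACGTN":
                if a == "N" or b == "N":
                    m[a, b] = 0.0
                else:
                    m[a, b] = 1.0 if a == b else -1.0
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = m
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -1.0
        _LOCAL_ALIGNER = aligner
    return _LOCAL_ALIGNER


def local_align(query: str, target: str):
    """Best local alignment of ``query`` against ``target``.

    Returns ``(score, qstart, qend, tstart, tend, matches, columns)`` with
    half-open coordinates; ``columns`` counts aligned positions including
    internal gaps.  Returns all zeros when nothing aligns.
    """
    aligner = _local_aligner()
    score = aligner.score(query, target)
    if score <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    aln = aligner.align(query, target)[0]
    qblocks, tblocks = aln.aligned
    matches = 0
    columns = 0
    prev_q = prev_t = None
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        if prev_q is not None:
            columns += (q0 - prev_q) + (t0 - prev_t)  # internal gaps
        for qa, ta in zip(query[q0:q1], target[t0:t1]):
            columns += 1
            if qa == ta and qa != "N":
                matches += 1
        prev_q, prev_t = q1, t1
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    return int(score), qstart, qend, tstart, tend, matches, columns


def _seed_clusters(query: str, target: str, k: int, band: int = 24):
    """Diagonal vote clusters of exact k-mer seeds; returns [(votes, diag)]."""
    index: dict[str, list[int]] = {}
    for qp in range(len(query) - k + 1):
        index.setdefault(query[qp : qp + k], []).append(qp)
    votes: dict[int, int] = {}
    for tp in range(len(target) - k + 1):
        hits = index.get(target[tp : tp + k])
        if hits:
            for qp in hits:
                d = (tp - qp) // band
                votes[d] = votes.get(d, 0) + 1
    return sorted(((v, d) for d, v in votes.items()), reverse=True)


def locate_region(
    genome: AnnotatedMitogenome,
    query: str,
    gene_name: str = "",
    k: int = 11,
    min_coverage: float = 0.8,
    min_identity: float = 0.7,
    max_clusters: int = 4,
    band: int = 24,
) -> RegionHit | None:
    """Find a query gene in a genome by seed-and-extend local alignment.

    Exact k-mer seeds (k=11) on both strands vote for diagonals; the best
    diagonal clusters are refined by affine-gap local alignment
    (match +1, mismatch −1, gap open −2, extend −1).  The best-scoring hit
    is returned if it covers ≥ ``min_coverage`` of the query at
    ≥ ``min_identity`` identity; ties go to the leftmost start, then to
    the + strand.
    """
    if len(query) < 30:
        raise ValueError("query must be at least 30 bp")
    if set(query) - set("ACGTN"):
        raise ValueError("query contains non-ACGTN symbols")
    target = genome.sequence
    pad = max(50, len(query) // 5)
    best = None  # (score, start, strand_rank, hit)
    for strand in "+-":
        qs = query if strand == "+" else reverse_complement(query)
        clusters = _seed_clusters(qs, target, k, band)[:max_clusters]
        for votes, d in clusters:
            t0 = max(0, d * band - pad)
            t1 = min(len(target), d * band + len(qs) + band + pad)
            window = target[t0:t1]
            score, q0, q1, w0, w1, m, cols = local_align(qs, window)
            if score <= 0 or cols == 0:
                continue
            g0, g1 = t0 + w0, t0 + w1
            identity = m / cols
            coverage = (q1 - q0) / len(qs)
            cand = (score, -g0, 1 if strand == "+" else 0)
            hit = RegionHit(
                genome.genome_id,
                gene_name,
                g0,
                g1,
                strand,
                identity,
                coverage,
            )
            if best is None or cand > best[0]:
                best = (cand, hit)
    if best is None:
        return None
    hit = best[1]
    if hit.coverage_fraction >= min_coverage and hit.identity_fraction >= min_identity:
        return hit
    return None


# ---------------------------------------------------------------------------
# core construction


def shared_gene_set(
    genomes: Sequence[AnnotatedMitogenome],
    reference: AnnotatedMitogenome,
    min_coverage: float = 0.8,
    min_identity: float = 0.7,
) -> list[str]:
    """Reference genes present (annotated or locatable) in every genome,
    ordered by reference coordinate."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ref_feats = sorted(reference.features, key=lambda f: (f.start, f.name))
    kept = []
    for f in ref_feats:
        query = reference.feature_sequence(f)
        ok = True
        for g in genomes:
            if g.genome_id == reference.genome_id or g.find_gene(f.name):
                continue
            if (
                locate_region(
                    g, query, f.name, min_coverage=min_coverage, min_identity=min_identity
                )
                is None
            ):
                ok = False
                break
        if ok:
            kept.append(f.name)
    if not kept:
        raise ValueError("no shared coding regions")
    return kept


def build_core_reference(
    reference: AnnotatedMitogenome, genes: Iterable[str]
) -> CoreReferenceSet:
    """Concatenate the reference CDS extents of ``genes`` in genome order.

    Minus-strand genes are reverse-complemented into the concatenation so
    the core is uniformly coding-strand.  Overlapping CDS extents keep both
    genes, with the overlap trimmed from the downstream region (warned).
    """
    feats = []
    for name in genes:
        f = reference.find_gene(name)
        if f is None:
            raise ValueError(f"gene {name} not annotated on reference")
        feats.append(f)
    feats.sort(key=lambda f: (f.start, f.name))
    regions, parts = [], []
    prev_end = -1
    for f in feats:
        start, end = f.start, f.end
        if start < prev_end:
            warnings.warn(
                f"CDS {f.name} overlaps previous region; trimming overlap"
            )
            start = prev_end
            if start >= end:
                continue
        raw = reference.sequence[start:end]
        seq = reverse_complement(raw) if f.strand == "-" else raw
        regions.append(CoreRegion(f.name, start, end - start, f.strand))
        parts.append(seq)
        prev_end = end
    return CoreReferenceSet(reference.genome_id, regions, "".join(parts))


def extract_core_sequence(
    genome: AnnotatedMitogenome,
    core: CoreReferenceSet,
    min_coverage: float = 0.8,
    min_identity: float = 0.7,
) -> CoreSequence:
    """Collect one sequence per core region from a genome.

    Preference order per region: the genome's own annotation, then a
    similarity-search rescue, then an N-fill of the reference length (the
    region is recorded as missing rather than dropping the sample).
    """
    seqs, prov, hits = [], [], []
    for i, region in enumerate(core.regions):
        f = genome.find_gene(region.gene_name)
        if f is not None:
            seqs.append(genome.feature_sequence(f))
            prov.append("annotated")
            hits.append(None)
            continue
        hit = locate_region(
            genome,
            core.region_sequence(i),
            region.gene_name,
            min_coverage=min_coverage,
            min_identity=min_identity,
        )
        if hit is not None:
            raw = genome.sequence[hit.start : hit.end]
            seqs.append(reverse_complement(raw) if hit.strand == "-" else raw)
            prov.append("rescued")
            hits.append(hit)
        else:
            seqs.append("N" * region.length)
            prov.append("missing")
            hits.append(None)
    return CoreSequence(genome.genome_id, seqs, prov, hits)
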