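"""Synthetic mitogenome populations with known truth.

The generator emulates the statistical structure of yeast mitochondrial
data that the rest of the package is built to handle:

* coding sequence with a strong AT bias (defaults A 30.95%, T 41.33%,
  C 13.09%, G 14.63%) and near-pure-AT repetitive intergenic spacers
  (tandem 8-mer repeats, 99% AT);
* variable gene content — per-genome gene deletion (the sequence is gone)
  and annotation dropout (the sequence is present but the feature record
  is not, the case the similarity-search rescue exists for);
* population structure under a symmetric island model, with migration
  set from a target Fst via the two-deme structured-coalescent
  calibration m = (1 − Fst)/(4 Fst), optional admixed individuals with
  known ancestry rows, recombination concentrated in intergenic
  intervals (hotspot multipliers on a background map), and random unread
  positions.

Everything is driven by one mandatory seed; identical configurations
yield byte-identical datasets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .align_qc import AlignmentMatrix
from .coalescent import RateMap, drop_mutations, simulate_arg
from .core_reference import AnnotatedMitogenome, GeneFeature

__all__ = [
    "DEFAULT_GENE_LAYOUT",
    "GENE_NAMES",
    "SimulationConfig",
    "SimulatedHaplotypes",
    "SimulatedDataset",
    "fst_to_migration",
    "simulate_haplotypes",
    "realize_genomes",
    "simulate_dataset",
    "inject_missingness",
    "variants_to_alignment",
]

#: The mitochondrial protein-coding gene set used for synthetic genomes.
GENE_NAMES = ("COX1", "COX2", "COX3", "COB", "ATP6", "ATP8", "ATP9", "VAR1")

#: (gene length, downstream intergenic length) pairs; gene sizes sum to
#: 5475 bp, the scale of a real concatenated mitogenome core.
DEFAULT_GENE_LAYOUT = (
    (900, 250),
    (750, 250),
    (810, 250),
    (660, 250),
    (540, 250),
    (600, 250),
    (615, 250),
    (600, 250),
)

DEFAULT_BASE_BIAS = {"A": 0.3095, "T": 0.4133, "C": 0.1309, "G": 0.1463}


def fst_to_migration(fst: float) -> float:
    """Per-lineage migration rate hitting a target Fst (two-deme island
    model, time scaled so a within-deme pair coalesces at rate 1):
    E[Fst] = 1/(1 + 4m), hence m = (1 − Fst)/(4 Fst)."""
    if not 0 < fst < 1:
        raise ValueError("target Fst must lie in (0, 1)")
    return (1.0 - fst) / (4.0 * fst)


@dataclass
class SimulationConfig:
    seed: int
    n_samples: int = 50  # per population
    n_populations: int = 1
    target_fst: float | None = None
    migration: float | None = None  # overrides target_fst when set
    admixture: tuple[tuple[float, ...], ...] = ()  # Q rows of extra samples
    theta: float = 38.6
    rho_background: float = 20.0
    hotspot_multipliers: dict[int, float] = field(default_factory=dict)
    gene_layout: tuple[tuple[int, int], ...] = DEFAULT_GENE_LAYOUT
    base_bias: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_BIAS))
    intergenic_at: float = 0.99
    missing_rate: float = 0.0
    pseudogene_dropout: float = 0.0
    annotation_dropout: float = 0.0
    forced_gene_deletion: tuple[tuple[int, str], ...] = ()
    forced_annotation_dropout: tuple[tuple[int, str], ...] = ()
    minus_strand_genes: tuple[str, ...] = ()
    transition_prob: float = 0.5
    allow_triallelic: bool = False

    def __post_init__(self):
        if self.seed is None or self.seed < 0:
            raise ValueError("a non-negative seed is mandatory")
        if abs(sum(self.base_bias.values()) - 1.0) > 1e-6:
            raise ValueError("base_bias must sum to 1")
        for p in (self.intergenic_at, self.missing_rate, self.pseudogene_dropout,
                  self.annotation_dropout, self.transition_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if len(self.gene_layout) > len(GENE_NAMES):
            raise ValueError(f"at most {len(GENE_NAMES)} genes supported")

    @property
    def genome_length(self) -> int:
        return sum(g + s for g, s in self.gene_layout)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return GENE_NAMES[: len(self.gene_layout)]

    def gene_coordinates(self) -> dict[str, tuple[int, int]]:
        """Gene extents on the base genome, 0-based half-open."""
        out, pos = {}, 0
        for name, (glen, slen) in zip(self.gene_names, self.gene_layout):
            out[name] = (pos, pos + glen)
            pos += glen + slen
        return out

    def intergenic_intervals(self) -> list[tuple[int, int]]:
        out, pos = [], 0
        for glen, slen in self.gene_layout:
            out.append((pos + glen, pos + glen + slen))
            pos += glen + slen
        return out

    def rate_map(self) -> RateMap:
        """Background rho spread uniformly over the genome, multiplied in
        hotspot intergenic intervals (keyed by intergenic index)."""
        L = self.genome_length
        breaks, rates = [0.0], []
        density = self.rho_background  # per unit of the [0,1) genome
        segments = []
        pos = 0
        for idx, (glen, slen) in enumerate(self.gene_layout):
            segments.append((pos, pos + glen, 1.0))
            mult = self.hotspot_multipliers.get(idx, 1.0)
            segments.append((pos + glen, pos + glen + slen, mult))
            pos += glen + slen
        for a, b, mult in segments:
            if b == a:
                continue
            breaks.append(b / L)
            rates.append(density * mult)
        return RateMap(breaks, rates)


@dataclass
class SimulatedHaplotypes:
    positions: np.ndarray  # bp position per site, strictly increasing
    genotypes: np.ndarray  # samples x sites, allele index (0 ancestral)
    n_alleles: np.ndarray  # alleles per site (2 or 3)
    labels: np.ndarray  # population index; -1 for admixed extras
    Q_true: np.ndarray  # samples x populations
    event_positions: np.ndarray  # bp position of every recombination event
    genome_length: int
    config: SimulationConfig


def simulate_haplotypes(config: SimulationConfig) -> SimulatedHaplotypes:
    """Coalescent haplotypes on the configured genome.

    Infinite-sites mutations are thinned onto base-pair positions (at most
    one retained per bp, or two when triallelic sites are enabled); every
    recombination event is logged with its physical position.
    """
    rng = random.Random(config.seed)
    n_pops = config.n_populations
    migration = config.migration
    if n_pops > 1 and migration is None:
        if config.target_fst is None:
            raise ValueError("multiple populations need migration or target_fst")
        # target Fst of 0 means a panmictic population carrying deme labels
        migration = None if config.target_fst <= 0 else fst_to_migration(config.target_fst)
    if n_pops <= 1 or migration is None:
        arg = simulate_arg(
            [config.n_samples * n_pops], rate_map=config.rate_map(), rng=rng
        )
    else:
        arg = simulate_arg(
            [config.n_samples] * n_pops,
            migration=migration,
            rate_map=config.rate_map(),
            rng=rng,
        )
    muts = drop_mutations(arg, config.theta, rng)
    L = config.genome_length
    n = config.n_samples * n_pops
    by_bp: dict[int, list] = {}
    for m in muts:
        bp = min(int(m.position * L), L - 1)
        bucket = by_bp.setdefault(bp, [])
        if len(bucket) == 0 or (config.allow_triallelic and len(bucket) == 1):
            bucket.append(m.carriers)
    positions = sorted(by_bp)
    geno = np.zeros((n, len(positions)), dtype=np.int8)
    n_alleles = np.ones(len(positions), dtype=np.int8)
    for s, bp in enumerate(positions):
        for allele, carriers in enumerate(by_bp[bp], start=1):
            for i in carriers:
                geno[i, s] = allele  # later mutation wins at shared carriers
            n_alleles[s] = allele + 1
    labels = np.repeat(np.arange(n_pops), config.n_samples)
    Q = np.zeros((n, n_pops))
    Q[np.arange(n), labels] = 1.0

    # admixed extras: per-site donor population drawn by the Q row
    if config.admixture:
        extra_rows = []
        for q_row in config.admixture:
            if len(q_row) != n_pops or abs(sum(q_row) - 1.0) > 1e-9:
                raise ValueError("admixture rows must be simplex vectors over populations")
            row = np.zeros(len(positions), dtype=np.int8)
            for s in range(len(positions)):
                pop = _categorical(q_row, rng)
                donor = pop * config.n_samples + rng.randrange(config.n_samples)
                row[s] = geno[donor, s]
            extra_rows.append(row)
        geno = np.vstack([geno, np.array(extra_rows, dtype=np.int8)])
        labels = np.concatenate([labels, -np.ones(len(config.admixture), dtype=int)])
        Q = np.vstack([Q, np.array([list(q) for q in config.admixture])])

    events = np.array(
        sorted(min(int(p * L), L - 1) for _, p in arg.recombination_events), dtype=int
    )
    return SimulatedHaplotypes(
        np.array(positions, dtype=int),
        geno,
        n_alleles,
        labels,
        Q,
        events,
        L,
        config,
    )


def _categorical(weights, rng: random.Random) -> int:
    u = rng.random()
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1


def _weighted_base(bias: dict[str, float], rng: random.Random) -> str:
    u = rng.random()
    acc = 0.0
    for b in "ACGT":
        acc += bias[b]
        if u < acc:
            return b
    return "T"


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _derived_base(ref: str, exclude: set[str], config, rng: random.Random) -> str:
    """Mutant base: transition with the configured probability, otherwise a
    random transversion; never colliding with ``exclude``."""
    while True:
        if rng.random() < config.transition_prob:
            b = _TRANSITION[ref]
        else:
            tv = [x for x in "ACGT" if x != ref and x != _TRANSITION[ref]]
            b = tv[rng.randrange(2)]
        if b not in exclude:
            return b


@dataclass
class SimulatedDataset:
    reference: AnnotatedMitogenome
    genomes: list[AnnotatedMitogenome]
    sample_ids: list[str]
    haplotypes: SimulatedHaplotypes
    base_genome: str
    site_alleles: list[list[str]]  # per site: [ancestral, derived, ...]
    gene_truth: dict[str, dict[str, tuple[int, int]]]  # genome -> gene -> extent
    deleted: list[tuple[str, str]]  # (sample_id, gene) with sequence removed
    unannotated: list[tuple[str, str]]  # (sample_id, gene) annotation dropped


def realize_genomes(
    haps: SimulatedHaplotypes, config: SimulationConfig | None = None
) -> SimulatedDataset:
    """Write the haplotypes onto AT-biased annotated genomes.

    The base genome has biased coding composition inside genes and
    tandem-repetitive, almost-pure-AT spacers between them.  Gene deletion
    removes the gene's sequence (shifting downstream coordinates);
    annotation dropout keeps the sequence but drops the feature record.
    The pristine annotated base genome is returned as the reference.
    """
    config = config or haps.config
    rng = random.Random(config.seed + 1)
    L = config.genome_length

    # base genome: genes with coding bias, spacers as AT-rich tandem repeats
    parts = []
    for glen, slen in config.gene_layout:
        parts.append("".join(_weighted_base(config.base_bias, rng) for _ in range(glen)))
        unit = "".join(rng.choice("AT") for _ in range(8))
        spacer = list((unit * (slen // 8 + 1))[:slen])
        for i in range(slen):
            if rng.random() > config.intergenic_at:
                spacer[i] = rng.choice("CG")
        parts.append("".join(spacer))
    base = "".join(parts)

    # per-site allele bases (ancestral = base genome, derived drawn once)
    site_alleles: list[list[str]] = []
    for s, bp in enumerate(haps.positions):
        ref = base[bp]
        alleles = [ref]
        for _ in range(int(haps.n_alleles[s]) - 1):
            alleles.append(_derived_base(ref, set(alleles), config, rng))
        site_alleles.append(alleles)

    coords = config.gene_coordinates()
    features = [
        GeneFeature(
            name,
            a,
            b,
            "-" if name in config.minus_strand_genes else "+",
        )
        for name, (a, b) in coords.items()
    ]
    reference = AnnotatedMitogenome("REF", base, features, circular=True)

    n = haps.genotypes.shape[0]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    deleted, unannotated = [], []
    drop_del = {(i, g) for i, g in config.forced_gene_deletion}
    drop_ann = {(i, g) for i, g in config.forced_annotation_dropout}
    for i in range(n):
        for g in config.gene_names:
            if config.pseudogene_dropout and rng.random() < config.pseudogene_dropout:
                drop_del.add((i, g))
            elif config.annotation_dropout and rng.random() < config.annotation_dropout:
                drop_ann.add((i, g))

    genomes = []
    gene_truth: dict[str, dict[str, tuple[int, int]]] = {}
    for i, sid in enumerate(sample_ids):
        seq = list(base)
        for s, bp in enumerate(haps.positions):
            allele = int(haps.genotypes[i, s])
            if allele > 0:
                seq[bp] = site_alleles[s][allele]
        # apply deletions right-to-left so coordinates shift predictably
        removed = sorted(
            (coords[g] for (j, g) in drop_del if j == i), reverse=True
        )
        seq_str = "".join(seq)
        for a, b in removed:
            seq_str = seq_str[:a] + seq_str[b:]
        shift_of = lambda x: sum(
            min(b, x) - a for a, b in removed if a < x
        )
        feats, truth = [], {}
        for f in features:
            gone = any(coords[f.name] == (a, b) for a, b in removed)
            if gone:
                deleted.append((sid, f.name))
                continue
            a, b = coords[f.name]
            a2, b2 = a - shift_of(a), b - shift_of(b)
            truth[f.name] = (a2, b2)
            if (i, f.name) in drop_ann:
                unannotated.append((sid, f.name))
                continue
            feats.append(GeneFeature(f.name, a2, b2, f.strand))
        genomes.append(AnnotatedMitogenome(sid, seq_str, feats, circular=True))
        gene_truth[sid] = truth
    return SimulatedDataset(
        reference,
        genomes,
        sample_ids,
        haps,
        base,
        site_alleles,
        gene_truth,
        deleted,
        unannotated,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    return realize_genomes(simulate_haplotypes(config), config)


def inject_missingness(aln: AlignmentMatrix, rate: float, seed: int):
    """Replace each cell independently by N with probability ``rate``.

    Returns the masked alignment plus the boolean mask, so imputation can
    be scored against the truth.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0,1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(aln.codes.shape) < rate
    codes = aln.codes.copy()
    codes[mask] = ord("N")
    return AlignmentMatrix(list(aln.sample_ids), codes, aln.column_map.copy()), mask


def variants_to_alignment(
    dataset_or_haps, sample_ids=None, coding_only: bool = True
) -> AlignmentMatrix:
    """SNP-columns-only alignment straight from simulated haplotypes.

    Columns are the segregating base-pair positions with their realized
    allele bases; this skips genome realization for analyses that only
    need the variant matrix (Fst, PCA, ancestry, LD calibration).  By
    default only sites inside genes are kept — the mirror of the real
    pipeline, whose core covers coding regions only, so intergenic
    recombination falls between the flanking genes' SNPs
    (``coding_only=False`` keeps every segregating site).
    """
    if isinstance(dataset_or_haps, SimulatedDataset):
        haps = dataset_or_haps.haplotypes
        site_alleles = dataset_or_haps.site_alleles
        sample_ids = sample_ids or dataset_or_haps.sample_ids
    else:
        haps = dataset_or_haps
        # deterministic allele letters without genome realization
        rng = random.Random(haps.config.seed + 2)
        site_alleles = []
        for s in range(len(haps.positions)):
            ref = _weighted_base(haps.config.base_bias, rng)
            alleles = [ref]
            for _ in range(int(haps.n_alleles[s]) - 1):
                alleles.append(_derived_base(ref, set(alleles), haps.config, rng))
            site_alleles.append(alleles)
        n = haps.genotypes.shape[0]
        sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    keep = range(len(haps.positions))
    positions = haps.positions
    if coding_only:
        genes = haps.config.gene_coordinates().values()
        keep = [
            s
            for s, bp in enumerate(haps.positions)
            if any(a <= bp < b for a, b in genes)
        ]
        positions = haps.positions[keep]
    rows = []
    for i in range(haps.genotypes.shape[0]):
        rows.append(
            "".join(site_alleles[s][int(haps.genotypes[i, s])] for s in keep)
        )
    return AlignmentMatrix.from_strings(list(sample_ids), rows, positions)
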