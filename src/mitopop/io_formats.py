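"""External formats: GenBank/FASTA genomes, BED region maps, VCF variants,
TSV metadata, Newick trees, JSON run configuration, and run logging.

Coordinate conventions: everything in memory is 0-based half-open; BED
output is 0-based half-open; human-readable reports print 1-based first
positions and sizes (the convention used for annotated mitogenome maps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_reference import (
    AnnotatedMitogenome,
    CoreReferenceSet,
    CoreRegion,
    CoreSequence,
    GeneFeature,
)

__all__ = [
    "SOURCE_GROUPS",
    "GEO_GROUPS",
    "SampleMetadata",
    "RunConfig",
    "ParseError",
    "read_annotated_genome",
    "write_genbank",
    "write_region_map",
    "read_region_map",
    "bed_interval",
    "report_interval",
    "write_variants_vcf",
    "read_variants_vcf",
    "read_metadata",
    "write_metadata",
    "write_core_fasta",
    "read_core_fasta",
    "write_alignment_fasta",
    "write_newick",
    "read_newick",
    "setup_logging",
]

#: The eight technological source categories used to group strains.
SOURCE_GROUPS = (
    "wine_and_vine",
    "laboratory",
    "natural",
    "clinical",
    "other_fermented_beverages",
    "beer",
    "sake",
    "bread",
)

#: Geographical groups (the published labels; extensible by the caller).
GEO_GROUPS = (
    "Africa_Central",
    "Africa_Eastern",
    "Africa_West",
    "America_North",
    "America_South",
    "East_Asia",
    "Island_Southeast_Asia",
    "Asia_Japan",
    "Mainland_Southeast_Asia",
    "Europe_Britain",
    "Central_Europe",
    "Europe_Eastern",
    "Europe_Mediterranean",
    "Europe_Western",
    "Near_East_and_Caucasus",
    "Oceania",
)


class ParseError(ValueError):
    """Malformed input file; message names the file and, when known, the line."""


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample labels: technological source and geographical origin.

    Labels must come from the declared vocabularies (or be "unknown");
    vocabularies default to the module-level group lists.
    """

    sample_id: str
    source_group: str = "unknown"
    geo_group: str = "unknown"

    def validate(self, source_vocab=SOURCE_GROUPS, geo_vocab=GEO_GROUPS):
        if self.source_group != "unknown" and self.source_group not in source_vocab:
            raise ValueError(f"unknown source_group {self.source_group!r}")
        if self.geo_group != "unknown" and self.geo_group not in geo_vocab:
            raise ValueError(f"unknown geo_group {self.geo_group!r}")
        return self


@dataclass
class RunConfig:
    """Thresholds and seeds governing a full run.

    Defaults: samples with more than 10% unread positions are dropped,
    LD/structure analyses keep SNPs with minor-allele frequency above 10%,
    PCA reports 10 components, ancestry is fit for K = 2..6, and every
    stochastic operation is driven by ``seed``.
    """

    max_missing_fraction: float = 0.10
    min_maf: float = 0.10
    n_pcs: int = 10
    k_min: int = 2
    k_max: int = 6
    seed: int = 0
    rescue_min_coverage: float = 0.8
    rescue_min_identity: float = 0.7
    impute_neighbors: int = 5
    impute_min_informative: int = 3

    def __post_init__(self):
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must lie in [0,1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0,0.5]")
        if self.n_pcs < 1 or self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("bad n_pcs / K range")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def to_json(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path):
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# annotated genomes


def read_annotated_genome(path, feature_table=None) -> AnnotatedMitogenome:
    """Read one annotated mitogenome.

    ``path`` is a GenBank flat file, or a FASTA accompanied by a sidecar
    TSV ``feature_table`` (columns: gene, start, end, strand; 1-based
    inclusive coordinates).  CDS features without a gene/product name are
    kept under a synthesized name with a warning.  Topology defaults to
    circular.
    """
    from Bio import SeqIO

    path = Path(path)
    if feature_table is None:
        try:
            record = next(SeqIO.parse(str(path), "genbank"))
        except StopIteration:
            raise ParseError(f"{path}: no GenBank record found")
        except ValueError as e:
            raise ParseError(f"{path}: malformed GenBank record: {e}") from e
        features = []
        n_anon = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            name = (quals.get("gene") or quals.get("product") or [None])[0]
            if not name:
                n_anon += 1
                name = f"CDS_{n_anon}"
                warnings.warn(
                    f"{path}: CDS without gene/product name; using {name}"
                )
            strand = "-" if feat.location.strand == -1 else "+"
            parts = feat.location.parts
            if len(parts) > 1 and int(parts[0].start) > int(parts[-1].start):
                # join(end..origin, origin..start): spans the circular origin
                features.append(
                    GeneFeature(
                        name,
                        int(parts[0].start),
                        int(parts[-1].end),
                        strand,
                        wrap=True,
                    )
                )
            else:
                features.append(
                    GeneFeature(
                        name, int(feat.location.start), int(feat.location.end), strand
                    )
                )
        topology = record.annotations.get("topology", "circular")
        return AnnotatedMitogenome(
            record.id, str(record.seq).upper(), features, topology != "linear"
        )
    # FASTA + sidecar table
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ParseError(f"{path}: no FASTA record found")
    features = []
    for lineno, line in enumerate(Path(feature_table).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ParseError(f"{feature_table}: line {lineno}: expected 4 columns")
        name, start1, end1, strand = fields[:4]
        try:
            start1, end1 = int(start1), int(end1)
        except ValueError:
            raise ParseError(
                f"{feature_table}: line {lineno}: non-integer coordinates"
            )
        if start1 <= end1:
            features.append(GeneFeature(name, start1 - 1, end1, strand))
        else:  # wraps the origin
            features.append(GeneFeature(name, start1 - 1, end1, strand, wrap=True))
    return AnnotatedMitogenome(record.id, str(record.seq).upper(), features, True)


def write_genbank(genome: AnnotatedMitogenome, path) -> None:
    """Emit a minimal GenBank flat file (sequence + CDS features)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description="synthetic mitogenome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wrap:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start, len(genome.sequence), strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        record.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": [f.name]})
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# region maps


def bed_interval(first_base_1: int, size: int) -> tuple[int, int]:
    """1-based first base + size -> BED 0-based half-open interval."""
    return first_base_1 - 1, first_base_1 - 1 + size


def report_interval(start0: int, end0: int) -> tuple[int, int]:
    """BED interval -> 1-based first base + size (inverse of bed_interval)."""
    return start0 + 1, end0 - start0


def write_region_map(core: CoreReferenceSet, bed_path, report_path=None) -> None:
    """Emit the core regions as BED plus a 1-based position/size report.

    The report mirrors the published map convention: the first base pair of
    each region on the genome and its size in brackets.
    """
    if not core.regions:
        raise ValueError("empty region set")
    regions = sorted(core.regions, key=lambda r: r.ref_start)
    for a, b in zip(regions, regions[1:]):
        if b.ref_start < a.ref_start + a.length:
            raise ValueError(f"regions {a.gene_name} and {b.gene_name} overlap")
    with open(bed_path, "w") as fh:
        for r in regions:
            s0, e0 = bed_interval(r.ref_start + 1, r.length)
            fh.write(f"{core.reference_id}\t{s0}\t{e0}\t{r.gene_name}\t0\t{r.strand}\n")
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write("gene\tfirst_base\tsize\tstrand\n")
            for r in regions:
                fh.write(f"{r.gene_name}\t{r.ref_start + 1}\t{r.length}\t{r.strand}\n")


def read_region_map(report_path) -> list[CoreRegion]:
    """Read back the report table written by :func:`write_region_map`."""
    regions = []
    for lineno, line in enumerate(Path(report_path).read_text().splitlines(), 1):
        if lineno == 1 or not line.strip():
            continue
        try:
            gene, first, size, strand = line.split("\t")
            regions.append(CoreRegion(gene, int(first) - 1, int(size), strand))
        except ValueError as e:
            raise ParseError(f"{report_path}: line {lineno}: {e}") from e
    return regions


# ---------------------------------------------------------------------------
# VCF (minimal haploid subset of VCF 4.2)


def write_variants_vcf(variants, path, reference_id="core") -> None:
    """Write a VariantTable as minimal VCF 4.2 with haploid GT calls.

    POS is the 1-based core coordinate; multiallelic sites are one record
    with comma-separated ALTs; unread calls are ``.``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference_id}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.sample_ids)
            + "\n"
        )
        for s in range(variants.n_sites):
            alleles = variants.alleles[s]
            ref, alts = alleles[0], alleles[1:]
            gts = [
                "." if g < 0 else str(int(g)) for g in variants.genotypes[:, s]
            ]
            fh.write(
                f"{reference_id}\t{int(variants.columns[s]) + 1}\t.\t{ref}\t"
                f"{','.join(alts) if alts else '.'}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_variants_vcf(path):
    """Read back a VCF written by :func:`write_variants_vcf`."""
    from .popgen_stats import VariantTable

    sample_ids = None
    columns, alleles, rows = [], [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            sample_ids = line.split("\t")[9:]
            continue
        if sample_ids is None:
            raise ParseError(f"{path}: line {lineno}: missing #CHROM header")
        fields = line.split("\t")
        if len(fields) != 9 + len(sample_ids):
            raise ParseError(f"{path}: line {lineno}: bad column count")
        columns.append(int(fields[1]) - 1)
        site_alleles = [fields[3]] + ([] if fields[4] == "." else fields[4].split(","))
        alleles.append(site_alleles)
        rows.append([-1 if g == "." else int(g) for g in fields[9:]])
    genotypes = np.array(rows, dtype=np.int8).T if rows else np.zeros((0, 0), np.int8)
    return VariantTable(
        sample_ids=list(sample_ids),
        columns=np.array(columns, dtype=int),
        alleles=alleles,
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# metadata, FASTA, Newick


def read_metadata(path, source_vocab=SOURCE_GROUPS, geo_vocab=GEO_GROUPS):
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    required = {"sample_id", "source_group", "geo_group"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    return [
        SampleMetadata(r.sample_id, r.source_group, r.geo_group).validate(
            source_vocab, geo_vocab
        )
        for r in df.itertuples()
    ]


def write_metadata(metadata, path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.source_group, m.geo_group) for m in metadata],
        columns=["sample_id", "source_group", "geo_group"],
    ).to_csv(path, sep="\t", index=False)


def write_core_fasta(core_seqs: list[CoreSequence], core, path) -> None:
    """Per-sample core material, one record per (sample, region)."""
    with open(path, "w") as fh:
        for cs in core_seqs:
            for i, (seq, prov) in enumerate(zip(cs.region_seqs, cs.provenance)):
                gene = core.regions[i].gene_name
                fh.write(f">{cs.genome_id}|{i}|{gene}|{prov}\n{seq}\n")


def read_core_fasta(path) -> list[CoreSequence]:
    from Bio import SeqIO

    by_sample: dict[str, list] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, idx, gene, prov = rec.id.split("|")
        by_sample.setdefault(sample, []).append((int(idx), str(rec.seq), prov))
    out = []
    for sample, items in by_sample.items():
        items.sort()
        out.append(
            CoreSequence(
                sample,
                [s for _, s, _ in items],
                [p for _, _, p in items],
                [None] * len(items),
            )
        )
    return out


def write_alignment_fasta(aln, path) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(aln.sample_ids):
            fh.write(f">{sid}\n{aln.row_string(i)}\n")


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def setup_logging(seed: int, logfile=None, level=logging.INFO) -> logging.Logger:
    """Line-oriented run log; the seed is recorded up front."""
    logger = logging.getLogger("mitopop")
    logger.setLevel(level)
    handler = logging.FileHandler(logfile) if logfile else logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.info("run seed: %d", seed)
    return logger
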