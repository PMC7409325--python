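"""End-to-end pipeline: reference construction → extraction → alignment/QC
→ summary statistics → LD/recombination → structure.

Stages communicate through files in the output directory so any stage can
be re-run independently, and a manifest records every artifact with its
SHA-256 along with parameters and the seed; deterministic stages
reproduce identical hashes on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import align_qc, core_reference, io_formats, ld_recomb, popgen_stats, structure
from .io_formats import RunConfig

__all__ = ["PipelineError", "PipelineManifest", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineManifest:
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, params: dict, inputs: list, outputs: list):
        self.stages.append(
            {
                "stage": name,
                "params": params,
                "inputs": {str(p): _sha256(p) for p in inputs},
                "outputs": {str(p): _sha256(p) for p in outputs},
                "timestamp": time.time(),
            }
        )

    def stage_hashes(self) -> dict[str, dict]:
        """Input/output hashes per stage (timestamps excluded) for
        determinism comparisons."""
        return {
            s["stage"]: {"inputs": s["inputs"], "outputs": s["outputs"]}
            for s in self.stages
        }

    def save(self, path):
        Path(path).write_text(json.dumps({"seed": self.seed, "stages": self.stages}, indent=2))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    genomes_dir,
    metadata_path=None,
    out_dir="mitopop_out",
    reference_id: str | None = None,
    recomb_table: "ld_recomb.TwoLocusTable | None" = None,
) -> PipelineManifest:
    """Run every stage on a directory of GenBank mitogenomes.

    ``reference_id`` picks the reference genome (default: a genome named
    REF if present, else the first by id).  ``recomb_table`` enables the
    recombination-intensity stage; without it only the Rm bound is
    profiled.  Any stage failure halts the run; the manifest (written to
    ``out_dir/manifest.json``) records the completed stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest(config.seed)
    log = io_formats.setup_logging(config.seed, out / "run.log")
    stage = "build-ref"
    try:
        genome_files = sorted(Path(genomes_dir).glob("*.gb*"))
        if len(genome_files) < 3:
            raise ValueError("need at least 3 genomes")
        genomes = [io_formats.read_annotated_genome(p) for p in genome_files]
        by_id = {g.genome_id: g for g in genomes}
        if reference_id is None:
            reference_id = "REF" if "REF" in by_id else sorted(by_id)[0]
        reference = by_id[reference_id]
        samples = [g for g in genomes if g.genome_id != reference_id]
        genes = core_reference.shared_gene_set(
            samples,
            reference,
            min_coverage=config.rescue_min_coverage,
            min_identity=config.rescue_min_identity,
        )
        core = core_reference.build_core_reference(reference, genes)
        io_formats.write_region_map(core, out / "core.bed", out / "core_regions.tsv")
        log.info("core reference: %d genes, %d bp", len(core.regions), core.total_length)
        manifest.record(stage, {"reference": reference_id}, genome_files,
                        [out / "core.bed", out / "core_regions.tsv"])

        stage = "extract"
        cores = [
            core_reference.extract_core_sequence(
                g, core,
                min_coverage=config.rescue_min_coverage,
                min_identity=config.rescue_min_identity,
            )
            for g in samples
        ]
        io_formats.write_core_fasta(cores, core, out / "cores.fasta")
        manifest.record(stage, {}, genome_files, [out / "cores.fasta"])

        stage = "align"
        aln, insertions, excluded = align_qc.anchor_align(core, cores)
        io_formats.write_alignment_fasta(aln, out / "alignment.fasta")
        manifest.record(stage, {"excluded": excluded}, [out / "cores.fasta"],
                        [out / "alignment.fasta"])

        stage = "qc"
        aln, report = align_qc.filter_missing_samples(aln, config.max_missing_fraction)
        aln = align_qc.impute_positions(
            aln, config.seed, config.impute_neighbors, config.impute_min_informative
        )
        io_formats.write_alignment_fasta(aln, out / "qc_alignment.fasta")
        with open(out / "missingness.tsv", "w") as fh:
            fh.write("sample_id\tmissing_fraction\tdropped\n")
            for sid, f in sorted(report.missing_fraction.items()):
                fh.write(f"{sid}\t{f:.6f}\t{int(sid in report.dropped_samples)}\n")
        log.info("qc: %d samples dropped", len(report.dropped_samples))
        manifest.record(stage, {"max_missing": config.max_missing_fraction},
                        [out / "alignment.fasta"],
                        [out / "qc_alignment.fasta", out / "missingness.tsv"])

        stage = "stats"
        summary = popgen_stats.summarize_diversity(aln)
        taj = popgen_stats.tajimas_D(aln, seed=config.seed, n_simulations=1000)
        fs = popgen_stats.fus_Fs(aln, seed=config.seed)
        with open(out / "summary.tsv", "w") as fh:
            fh.write("statistic\tvalue\n")
            for key, val in [
                ("n_sequences", summary.n_sequences),
                ("length_bp", summary.length_bp),
                ("polymorphic_sites", summary.n_polymorphic_sites),
                ("n_haplotypes", summary.n_haplotypes),
                ("gene_diversity", f"{summary.gene_diversity:.6f}"),
                ("gene_diversity_sd", f"{summary.gene_diversity_sd:.6f}"),
                ("mean_pairwise_differences", f"{summary.mean_pairwise_differences:.6f}"),
                ("nucleotide_diversity", f"{summary.nucleotide_diversity:.6f}"),
                ("transitions", summary.transitions),
                ("transversions", summary.transversions),
                ("tajimas_D", "NA" if taj is None else f"{taj.D:.6f}"),
                ("tajimas_D_p_beta", "NA" if taj is None else f"{taj.p_beta:.6f}"),
                ("fu_Fs", f"{fs.Fs:.6f}"),
                ("fu_Fs_p", f"{fs.p:.6f}"),
            ]:
                fh.write(f"{key}\t{val}\n")
        variants = popgen_stats.call_variants(aln)
        io_formats.write_variants_vcf(variants, out / "variants.vcf")
        manifest.record(stage, {}, [out / "qc_alignment.fasta"],
                        [out / "summary.tsv", out / "variants.vcf"])

        stage = "ld"
        filtered = ld_recomb.maf_filter(variants, config.min_maf)
        pairs = ld_recomb.compute_ld_pairs(filtered)
        with open(out / "ld.tsv", "w") as fh:
            fh.write("site_i\tsite_j\tD\tD_prime\tr2\tci_low\tci_high\tn\n")
            for p in pairs:
                fh.write(
                    f"{p.site_i}\t{p.site_j}\t{p.D:.6f}\t{p.D_prime:.4f}\t"
                    f"{p.r2:.4f}\t{p.ci_low:.3f}\t{p.ci_high:.3f}\t{p.n_informative}\n"
                )
        blocks = ld_recomb.gabriel_blocks(pairs, filtered.n_sites)
        with open(out / "blocks.bed", "w") as fh:
            for b in blocks:
                fh.write(
                    f"core\t{int(filtered.columns[b.first_site])}\t"
                    f"{int(filtered.columns[b.last_site]) + 1}\tblock\n"
                )
        if recomb_table is not None:
            profile = ld_recomb.recombination_intensity(filtered, recomb_table, config.seed)
        else:
            rm_total, cuts = ld_recomb.hudson_kaplan_rm(filtered)
            profile = ld_recomb.RecombinationProfile([], rm_total, cuts)
        with open(out / "recombination.tsv", "w") as fh:
            fh.write(f"# Rm_total\t{profile.rm_total}\n")
            fh.write("left_site\tright_site\tleft_pos\tright_pos\trm\trho_hat\tintensity\n")
            for iv in profile.intervals:
                fh.write(
                    f"{iv.left_site}\t{iv.right_site}\t{iv.left_pos}\t{iv.right_pos}\t"
                    f"{iv.rm_contribution}\t{iv.rho_hat}\t{iv.intensity}\n"
                )
        manifest.record(stage, {"min_maf": config.min_maf}, [out / "variants.vcf"],
                        [out / "ld.tsv", out / "blocks.bed", out / "recombination.tsv"])

        stage = "structure"
        gm = structure.encode_genotypes(filtered)
        res = structure.pca(gm, min(config.n_pcs, gm.n_samples - 1))
        rerun = structure.remove_outliers_and_rerun(res, gm)
        with open(out / "pca.tsv", "w") as fh:
            fh.write("sample_id\t" + "\t".join(f"PC{i+1}" for i in range(res.n_pcs)) + "\n")
            for i, sid in enumerate(rerun.sample_ids):
                fh.write(sid + "\t" + "\t".join(f"{x:.6f}" for x in rerun.coordinates[i]) + "\n")
        outputs = [out / "pca.tsv"]
        for K in range(config.k_min, config.k_max + 1):
            if K >= gm.n_samples:
                break
            anc = structure.nmf_ancestry(gm, K, seed=config.seed)
            qp = out / f"ancestry_K{K}.tsv"
            with open(qp, "w") as fh:
                fh.write("sample_id\t" + "\t".join(f"Q{i+1}" for i in range(K)) + "\n")
                for i, sid in enumerate(anc.sample_ids):
                    fh.write(sid + "\t" + "\t".join(f"{x:.6f}" for x in anc.Q[i]) + "\n")
            outputs.append(qp)
        dist = structure.pairwise_snp_distance(aln)
        tree = structure.neighbor_joining(dist, aln.sample_ids)
        io_formats.write_newick(tree, out / "nj.nwk")
        outputs.append(out / "nj.nwk")
        if metadata_path is not None:
            metadata = io_formats.read_metadata(metadata_path)
            for grouping in ("source_group", "geo_group"):
                labels = {getattr(m, grouping) for m in metadata} - {"unknown"}
                if len(labels) < 3:
                    continue
                fst_df, fst_tree = structure.group_fst_tree(aln, metadata, grouping)
                fst_df.to_csv(out / f"fst_{grouping}.tsv", sep="\t")
                io_formats.write_newick(fst_tree, out / f"fst_{grouping}.nwk")
                outputs += [out / f"fst_{grouping}.tsv", out / f"fst_{grouping}.nwk"]
        manifest.record(stage, {"n_pcs": config.n_pcs}, [out / "variants.vcf"], outputs)
    except Exception as e:  # noqa: BLE001 — manifest must record progress
        manifest.save(out / "manifest.json")
        raise PipelineError(stage, e) from e
    manifest.save(out / "manifest.json")
    return manifest
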