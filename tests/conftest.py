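"""Shared fixtures: small synthetic datasets and a small two-locus table."""

import pytest

from mitopop.ld_recomb import build_two_locus_table
from mitopop.simulate import SimulationConfig, simulate_dataset

SMALL_LAYOUT = tuple((180 + 20 * i, 60) for i in range(8))


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard core-extraction fixture: 8 genes, 20 genomes, one
    annotation-dropout (rescue case) and one true gene deletion."""
    cfg = SimulationConfig(
        seed=42,
        n_samples=20,
        theta=8.0,
        rho_background=5.0,
        gene_layout=SMALL_LAYOUT,
        forced_annotation_dropout=((3, "COX2"),),
        forced_gene_deletion=((7, "ATP6"),),
        minus_strand_genes=("COB",),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_two_locus_table():
    """A coarse sampling table (n=10) — enough for unit-level checks."""
    return build_two_locus_table(n=10, reps=8000, seed=3)
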