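import numpy as np
import pytest

from barnsplice import (
    AnnotationSet,
    GeneModel,
    SimulationConfig,
    TranscriptModel,
    simulate_annotation,
    simulate_droplets,
)


@pytest.fixture(scope="session")
def toy_annotation() -> AnnotationSet:
    """Two genes: an A gene with a skipped-exon isoform pair, a B gene with
    one single-exon transcript on the minus strand."""
    g1 = GeneModel(
        gene_id="AG1",
        species="A",
        chrom="A_chr1",
        strand="+",
        transcripts=[
            TranscriptModel("AG1.t1", "AG1", ((100, 300), (500, 600), (800, 1000))),
            TranscriptModel("AG1.t2", "AG1", ((100, 300), (800, 1000))),
        ],
    )
    g2 = GeneModel(
        gene_id="BG1",
        species="B",
        chrom="B_chr1",
        strand="-",
        transcripts=[TranscriptModel("BG1.t1", "BG1", ((2000, 3000),))],
    )
    return AnnotationSet([g1, g2])


@pytest.fixture(scope="session")
def small_sim():
    """One small full simulation with reads, shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_genes_per_species=20,
        n_cells_a=20,
        n_cells_b=20,
        n_empty_droplets=60,
        mean_counts_per_cell=400,
    )
    ann = simulate_annotation(cfg)
    matrix, reads, truth = simulate_droplets(cfg, ann)
    return cfg, ann, matrix, reads, truth
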