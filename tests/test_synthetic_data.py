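"""Simulator contracts: determinism, geometry, noise-model recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barnsplice import (
    AnnotationSet,
    ConfigError,
    GeneModel,
    SimulationConfig,
    TranscriptModel,
    simulate_annotation,
    simulate_droplets,
    simulate_reads_for_transcripts,
    write_gtf,
)


def brute_force_se_pairs(annotation):
    """Independent SE detector: exhaustive pairwise exon-set comparison.

    A pair (t_long, t_short) is an SE pair when t_short's exons equal
    t_long's minus exactly one internal exon.
    """
    found = set()
    for gene in annotation:
        for t1 in gene.transcripts:
            s1 = set(t1.exons)
            internal = set(t1.exons[1:-1])
            for t2 in gene.transcripts:
                if t2 is t1:
                    continue
                diff = s1 - set(t2.exons)
                if len(diff) == 1 and not (set(t2.exons) - s1):
                    (exon,) = diff
                    if exon in internal:
                        found.add((gene.gene_id, exon))
    return found


class TestAnnotation:
    def test_no_se_requested_means_no_se_pairs(self):
        ann = simulate_annotation(
            SimulationConfig(seed=2, n_genes_per_species=15, frac_genes_with_se=0.0)
        )
        assert brute_force_se_pairs(ann) == set()

    def test_full_se_two_isoforms_gives_exactly_one_pair_per_gene(self):
        ann = simulate_annotation(
            SimulationConfig(
                seed=3,
                n_genes_per_species=15,
                frac_genes_with_se=1.0,
                isoforms_per_gene=(2, 2),
            )
        )
        pairs = brute_force_se_pairs(ann)
        per_gene = pd.Series([g for g, _ in pairs]).value_counts()
        assert set(per_gene.index) == {g.gene_id for g in ann}
        assert (per_gene == 1).all()

    def test_same_seed_gives_identical_gtf_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_genes_per_species=10)
        for name in ("a.gtf", "b.gtf"):
            write_gtf(simulate_annotation(cfg), tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_infeasible_se_geometry_is_config_error(self):
        with pytest.raises(ConfigError, match="3 exons"):
            SimulationConfig(frac_genes_with_se=0.5, exons_per_transcript=(2, 2))

    def test_exon_count_and_isoform_count_respect_config(self):
        cfg = SimulationConfig(
            seed=4, n_genes_per_species=10, isoforms_per_gene=(2, 3),
            exons_per_transcript=(4, 6),
        )
        ann = simulate_annotation(cfg)
        for g in ann:
            assert 2 <= len(g.transcripts) <= 3
            assert 4 <= len(g.transcripts[0].exons) <= 6


class TestDroplets:
    def test_determinism_same_config_identical_outputs(self):
        cfg = SimulationConfig(
            seed=7, n_genes_per_species=8, n_cells_a=10, n_cells_b=10,
            n_empty_droplets=20, mean_counts_per_cell=150,
        )
        ann = simulate_annotation(cfg)
        m1, r1, t1 = simulate_droplets(cfg, ann)
        m2, r2, t2 = simulate_droplets(cfg, ann)
        assert (m1.counts != m2.counts).nnz == 0
        assert r1 == r2
        pd.testing.assert_frame_equal(t1.droplets, t2.droplets)
        pd.testing.assert_frame_equal(t1.reads, t2.reads)

    def test_matrix_counts_equal_kept_reads(self, small_sim):
        """Conservation: matrix total == non-duplicate, non-ambiguous reads."""
        _, _, matrix, reads, truth = small_sim
        kept = truth.reads[~truth.reads.is_duplicate & ~truth.reads.is_ambiguous]
        assert matrix.counts.sum() == len(kept)
        # and per droplet x gene, not just globally
        per = kept.groupby(["barcode", "gene_id"]).size()
        gid_to_col = {gid: j for j, (gid, _) in enumerate(matrix.genes)}
        bc_to_row = {bc: i for i, bc in enumerate(matrix.barcodes)}
        dense = matrix.counts.toarray()
        for (bc, gid), n in per.items():
            assert dense[bc_to_row[bc], gid_to_col[gid]] == n

    def test_pure_config_maps_each_droplet_to_one_species(self):
        cfg = SimulationConfig(
            seed=5, n_genes_per_species=10, n_cells_a=15, n_cells_b=15,
            n_empty_droplets=0, doublet_rate=0.0, ambient_fraction=0.0,
            contaminated_cell_rate=0.0, ambiguous_read_rate=0.0,
            mean_counts_per_cell=200, emit_reads=False,
        )
        ann = simulate_annotation(cfg)
        matrix, _, truth = simulate_droplets(cfg, ann)
        a, b = matrix.species_counts()
        is_a = truth.droplets.true_category.to_numpy() == "pureA"
        assert (b[is_a] == 0).all() and (a[~is_a] == 0).all()

    def test_ambient_contamination_recovered(self):
        """Mean cross-species fraction of pure cells ~= f * ambient cross share."""
        cfg = SimulationConfig(
            seed=13, n_genes_per_species=30, n_cells_a=500, n_cells_b=500,
            n_empty_droplets=0, doublet_rate=0.0, contaminated_cell_rate=0.0,
            ambient_fraction=0.05, mean_counts_per_cell=2000, emit_reads=False,
        )
        ann = simulate_annotation(cfg)
        matrix, _, truth = simulate_droplets(cfg, ann)
        a, b = matrix.species_counts()
        tot = matrix.totals()
        is_a = truth.droplets.true_category.to_numpy() == "pureA"
        cross = np.where(is_a, b, a) / tot
        expected = 0.05 * 0.5  # ambient pool is half cross-species at 500/500
        assert abs(cross.mean() - expected) / expected < 0.20

    def test_duplicate_and_ambiguous_rates_are_respected(self, small_sim):
        _, _, _, _, truth = small_sim
        t = truth.reads
        originals = t[~t.is_duplicate]
        n = len(originals)
        # binomial 4-sigma bands around the configured rates
        for col, rate in (("is_duplicate", 0.1), ("is_ambiguous", 0.01)):
            observed = t[col].sum() if col == "is_duplicate" else originals[col].sum()
            se = np.sqrt(rate * (1 - rate) * n)
            assert abs(observed - rate * n) < 4 * se


def _single_transcript_annotation(length=3000):
    t = TranscriptModel("AG1.t1", "AG1", ((1000, 1000 + length),))
    return AnnotationSet([GeneModel("AG1", "A", "A_chr1", "+", [t])])


class TestReadPlacement:
    def test_uniform_starts_at_lambda_zero(self):
        """Chi-square uniformity of fragment starts at lambda = 0, n = 50k."""
        ann = _single_transcript_annotation(3000)
        rng = np.random.default_rng(42)
        reads = simulate_reads_for_transcripts(
            ann, {"AG1.t1": 50_000}, rng, read_length=150, three_prime_bias=0.0
        )
        starts = np.array([r.blocks[0][0] - 1000 for r in reads])
        smax = 3000 - 150  # inclusive
        edges = np.linspace(0, smax + 1, 26)
        observed, _ = np.histogram(starts, bins=edges)
        expected = np.diff(np.floor(edges)) / (smax + 1) * 50_000
        # exact per-bin position counts as expectation
        counts = np.array(
            [np.floor(edges[i + 1]) - np.floor(edges[i]) for i in range(25)]
        )
        expected = counts / (smax + 1) * 50_000
        _, p = stats.chisquare(observed, expected)
        assert p > 1e-3

    def test_three_prime_bias_shifts_starts_monotonically(self):
        ann = _single_transcript_annotation(3000)
        means = []
        for lam in (0.0, 1.0, 3.0):
            rng = np.random.default_rng(7)
            reads = simulate_reads_for_transcripts(
                ann, {"AG1.t1": 20_000}, rng, read_length=150, three_prime_bias=lam
            )
            starts = np.array([r.blocks[0][0] - 1000 for r in reads])
            means.append(starts.mean() / (3000 - 150))
        assert means[0] < means[1] < means[2]

    def test_junction_spanning_reads_follow_exon_structure(self, toy_annotation):
        rng = np.random.default_rng(1)
        reads = simulate_reads_for_transcripts(
            toy_annotation, {"AG1.t2": 2000}, rng, read_length=150
        )
        spliced = [r for r in reads if len(r.blocks) > 1]
        assert spliced, "some fragments must cross the exon boundary"
        for r in spliced:
            assert r.blocks[0][1] == 300 and r.blocks[1][0] == 800
            assert r.aligned_length == 150
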