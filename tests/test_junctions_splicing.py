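"""Junction extraction/classification and skipped-exon quantification."""

import numpy as np
import pandas as pd
import pytest

from barnsplice import (
    JunctionRecord,
    ReadRecord,
    SelectionCriteria,
    SimulationConfig,
    classify_junctions,
    detect_se_events,
    extract_junctions,
    junction_concordance,
    quantify_se,
    select_genes,
    simulate_annotation,
    simulate_droplets,
    simulate_reads_for_transcripts,
)
from oracles import naive_junction_counts
from test_synthetic_data import brute_force_se_pairs


def _read(blocks, read_id="r1", chrom="A_chr1", barcode="BC"):
    return ReadRecord(chrom, tuple(blocks), barcode, read_id)


class TestExtraction:
    def test_gap_between_blocks_is_one_junction(self):
        (j,) = extract_junctions([_read([(100, 150), (200, 250)])])
        assert (j.chrom, j.donor, j.acceptor, j.count) == ("A_chr1", 150, 200, 1)

    def test_single_block_reads_yield_nothing(self):
        assert extract_junctions([_read([(100, 250)])]) == []

    def test_counts_match_per_read_gap_scan(self, small_sim):
        _, _, _, reads, _ = small_sim
        junctions = extract_junctions(reads)
        expected = naive_junction_counts(reads)
        assert {j.key: j.count for j in junctions} == expected
        # conservation: total junction count == number of block gaps
        assert sum(j.count for j in junctions) == sum(
            len(r.blocks) - 1 for r in reads
        )


class TestClassification:
    def test_transcript_intron_is_annotated(self, toy_annotation):
        (j,) = classify_junctions(
            [JunctionRecord("A_chr1", 300, 500, 1)], toy_annotation
        )
        assert j.status == "annotated" and j.gene_id == "AG1"

    def test_skip_junction_of_other_isoform_is_annotated(self, toy_annotation):
        (j,) = classify_junctions(
            [JunctionRecord("A_chr1", 300, 800, 1)], toy_annotation
        )
        assert j.status == "annotated"

    def test_one_bp_shift_makes_every_junction_novel(self, small_sim):
        _, ann, _, reads, _ = small_sim
        annotated = [
            j for j in classify_junctions(extract_junctions(reads), ann)
            if j.status == "annotated"
        ]
        assert annotated
        shifted = [
            JunctionRecord(j.chrom, j.donor + 1, j.acceptor + 1, j.count)
            for j in annotated
        ]
        reclassified = classify_junctions(shifted, ann)
        assert all(j.status == "novel" for j in reclassified)

    def test_novel_junction_inside_gene_span_gets_gene(self, toy_annotation):
        (j,) = classify_junctions(
            [JunctionRecord("A_chr1", 350, 450, 1)], toy_annotation
        )
        assert j.status == "novel" and j.gene_id == "AG1"

    def test_junction_outside_genes_unassigned(self, toy_annotation):
        (j,) = classify_junctions(
            [JunctionRecord("A_chr1", 5000, 6000, 1)], toy_annotation
        )
        assert j.status == "novel" and j.gene_id is None


class TestSeDetection:
    def test_constructed_se_pair_gives_exactly_one_event(self, toy_annotation):
        events = detect_se_events(toy_annotation)
        assert len(events) == 1
        ev = events[0]
        assert ev.gene_id == "AG1"
        assert ev.skipped_exon == (500, 600)
        assert ev.inclusion_junctions == ((300, 500), (600, 800))
        assert ev.exclusion_junction == (300, 800)

    def test_single_isoform_genes_have_no_events(self):
        ann = simulate_annotation(
            SimulationConfig(seed=2, n_genes_per_species=10, isoforms_per_gene=(1, 1))
        )
        assert detect_se_events(ann) == []

    def test_agrees_with_brute_force_pairwise_comparison(self):
        ann = simulate_annotation(
            SimulationConfig(seed=12, n_genes_per_species=30, frac_genes_with_se=0.7)
        )
        detected = {(e.gene_id, e.skipped_exon) for e in detect_se_events(ann)}
        assert detected == brute_force_se_pairs(ann)


class TestSeQuantification:
    def test_pure_inclusion_reads_give_proportion_one(self, toy_annotation):
        rng = np.random.default_rng(0)
        reads = simulate_reads_for_transcripts(toy_annotation, {"AG1.t1": 3000}, rng)
        events = quantify_se(detect_se_events(toy_annotation), extract_junctions(reads))
        assert events[0].inclusion_proportion == 1.0
        assert events[0].exclusion_count == 0

    def test_zero_support_reports_missing(self, toy_annotation):
        events = quantify_se(detect_se_events(toy_annotation), [])
        assert events[0].inclusion_proportion is None

    def test_seventy_thirty_mixture_recovered(self):
        """Read share ~ molecule weight x length; junction proportion ~ 0.7.

        The gene uses realistic proportions (skipped exon short relative to
        the transcript and the read length) so junction-crossing rates are
        comparable between isoforms.
        """
        from barnsplice import AnnotationSet, GeneModel, TranscriptModel

        exons = ((100, 800), (1200, 1260), (1500, 2740))  # 700 + 60 + 1240 bp
        ann = AnnotationSet(
            [
                GeneModel(
                    "AG1", "A", "A_chr1", "+",
                    [
                        TranscriptModel("AG1.t1", "AG1", exons),
                        TranscriptModel("AG1.t2", "AG1", (exons[0], exons[2])),
                    ],
                )
            ]
        )
        rng = np.random.default_rng(5)
        l1 = ann["AG1"].transcripts[0].length  # inclusion isoform
        l2 = ann["AG1"].transcripts[1].length
        w = np.array([0.7 * l1, 0.3 * l2])
        n1, n2 = rng.multinomial(5000, w / w.sum())
        reads = simulate_reads_for_transcripts(
            ann, {"AG1.t1": int(n1), "AG1.t2": int(n2)}, rng
        )
        (ev,) = quantify_se(detect_se_events(ann), extract_junctions(reads))
        n = ev.inclusion_count + ev.exclusion_count
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(ev.inclusion_proportion - 0.7) <= 3 * se


class TestGeneSelection:
    def test_published_threshold_examples(self):
        table = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4", "g5"],
                "has_SE": [True, True, False, True, True],
                "type_proportion": [0.6, 0.6, 0.9, 0.5, 0.6],
                "supporting_reads": [10, 10, 10, 10, 4],
                "tpm": [20.0, 16.0, 20.0, 20.0, 20.0],
            }
        )
        # g2: TPM not exceeding 16; g3: no SE; g4: proportion not exceeding 0.5;
        # g5: fewer than 5 supporting reads
        assert select_genes(table) == ["g1"]

    def test_agrees_with_brute_force_filter(self):
        rng = np.random.default_rng(9)
        n = 1000
        table = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "has_SE": rng.random(n) < 0.5,
                "type_proportion": rng.choice([0.3, 0.5, 0.51, 0.9], n),
                "supporting_reads": rng.integers(0, 12, n),
                "tpm": rng.choice([2.0, 16.0, 16.5, 100.0], n),
            }
        )
        crit = SelectionCriteria()
        expected = [
            row.gene_id
            for row in table.itertuples()
            if row.has_SE
            and row.type_proportion > 0.5
            and row.supporting_reads >= 5
            and row.tpm > 16
        ]
        assert select_genes(table, crit) == expected


class TestConcordance:
    def _sets(self, toy_annotation):
        rng = np.random.default_rng(4)
        reads = simulate_reads_for_transcripts(
            toy_annotation, {"AG1.t1": 2000, "AG1.t2": 1000}, rng
        )
        return classify_junctions(extract_junctions(reads), toy_annotation)

    def test_identical_sets_give_proportion_one(self, toy_annotation):
        ref = self._sets(toy_annotation)
        table = junction_concordance(ref, ref)
        assert (table["proportion"] == 1.0).all()

    def test_empty_query_gives_zero(self, toy_annotation):
        ref = self._sets(toy_annotation)
        table = junction_concordance([], ref)
        assert (table["proportion"] == 0.0).all()
        assert set(table["gene_id"]) == {"AG1"}
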