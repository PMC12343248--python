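"""Gene-body coverage profiles and genomic-region read assignment.

Coverage follows the metagene convention: each gene's representative (longest)
transcript is divided into 100 positional bins from 5' (bin 1) to 3'
(bin 100), respecting strand; every read base overlapping the transcript's
exons contributes one unit of base coverage to its bin. ``raw_depth`` is the
summed base coverage per bin over genes; the normalized profile is the
per-gene mean, divided by the total read count, log10-transformed with a
small pseudocount.

Region assignment labels every read exonic, intronic or intergenic by the
majority of its aligned bases, with precedence exonic > intronic > intergenic
on ties. "Intergenic" means outside every gene's span; intronic is inside a
span but outside all exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .types import AnnotationSet, ReadRecord

__all__ = ["CoverageProfile", "RegionFractions", "gene_body_coverage", "region_fractions"]


@dataclass
class CoverageProfile:
    raw_depth: np.ndarray  # summed base coverage per bin, over genes
    normalized: np.ndarray  # log10((mean over genes)/total reads + pseudocount)
    n_genes_covered: int
    total_reads: int

    @property
    def n_bins(self) -> int:
        return len(self.raw_depth)

    def mean_bin_index(self) -> float:
        """Depth-weighted mean 1-based bin index (50.5 = unbiased)."""
        bins = np.arange(1, self.n_bins + 1)
        return float((bins * self.raw_depth).sum() / self.raw_depth.sum())


@dataclass(frozen=True)
class RegionFractions:
    exonic: float
    intronic: float
    intergenic: float

    def __post_init__(self) -> None:
        if abs(self.exonic + self.intronic + self.intergenic - 1.0) > 1e-9:
            raise ValueError("region fractions must sum to 1")


def _representative_trees(
    annotation: AnnotationSet,
) -> tuple[dict[str, IntervalTree], list[int]]:
    """Interval trees over representative-transcript exons.

    Each tree entry maps a genomic exon to (gene index, transcript offset of
    the exon's first base in 5'->3' order, strand, transcript length, exon
    genomic bounds).
    """
    trees: dict[str, IntervalTree] = {}
    lengths: list[int] = []
    for gi, gene in enumerate(annotation):
        t = annotation.representative_transcript(gene.gene_id)
        lengths.append(t.length)
        exs = t.exons if gene.strand == "+" else t.exons[::-1]
        tree = trees.setdefault(gene.chrom, IntervalTree())
        offset = 0
        for gs, ge in exs:
            tree.addi(gs, ge, (gi, offset, gene.strand, t.length))
            offset += ge - gs
    return trees, lengths


def gene_body_coverage(
    reads: Iterable[ReadRecord],
    annotation: AnnotationSet,
    n_bins: int = 100,
    pseudocount: float = 1e-9,
) -> CoverageProfile:
    """Aggregate 5'->3' positional coverage over genes.

    Expects deduplicated, ambiguity-filtered reads. Raises if no read
    overlaps any representative transcript (no expressed genes).
    """
    trees, _ = _representative_trees(annotation)
    raw = np.zeros(n_bins, dtype=np.int64)
    covered = np.zeros(len(annotation), dtype=bool)
    total_reads = 0
    for r in reads:
        total_reads += 1
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for bs, be in r.blocks:
            for iv in tree.overlap(bs, be):
                gi, offset, strand, length = iv.data
                o1, o2 = max(bs, iv.begin), min(be, iv.end)
                gpos = np.arange(o1, o2)
                if strand == "+":
                    tpos = offset + (gpos - iv.begin)
                else:
                    tpos = offset + (iv.end - 1 - gpos)
                raw += np.bincount(tpos * n_bins // length, minlength=n_bins)
                covered[gi] = True
    n_cov = int(covered.sum())
    if n_cov == 0:
        raise ValueError("no expressed genes: no read overlaps a representative transcript")
    mean_over_genes = raw / n_cov
    normalized = np.log10(mean_over_genes / total_reads + pseudocount)
    return CoverageProfile(
        raw_depth=raw, normalized=normalized, n_genes_covered=n_cov, total_reads=total_reads
    )


def _covered_length(tree: IntervalTree | None, s: int, e: int) -> int:
    """Bases of [s, e) covered by a tree whose intervals are disjoint."""
    if tree is None:
        return 0
    return sum(min(e, iv.end) - max(s, iv.begin) for iv in tree.overlap(s, e))


def region_fractions(
    reads: Iterable[ReadRecord], annotation: AnnotationSet
) -> RegionFractions:
    """Fraction of reads assigned to exonic / intronic / intergenic regions."""
    exon_trees = annotation.exon_union_trees
    span_trees = {
        chrom: _merged(tree) for chrom, tree in annotation.gene_span_trees.items()
    }
    tallies = np.zeros(3, dtype=np.int64)  # exonic, intronic, intergenic
    n = 0
    for r in reads:
        n += 1
        exonic = genic = length = 0
        for bs, be in r.blocks:
            length += be - bs
            exonic += _covered_length(exon_trees.get(r.chrom), bs, be)
            genic += _covered_length(span_trees.get(r.chrom), bs, be)
        counts = (exonic, genic - exonic, length - genic)
        # majority wins; ties resolved by precedence exonic > intronic > intergenic
        tallies[max(range(3), key=lambda k: (counts[k], -k))] += 1
    if n == 0:
        raise ValueError("no reads to assign")
    frac = tallies / n
    return RegionFractions(float(frac[0]), float(frac[1]), float(frac[2]))


def _merged(tree: IntervalTree) -> IntervalTree:
    out = IntervalTree(tree)
    out.merge_overlaps(strict=False)
    return out
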