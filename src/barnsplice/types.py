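"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``. GTF's 1-based
closed coordinates are converted at the IO boundary and nowhere else.

Species are tagged ``"A"`` (human-like) and ``"B"`` (mouse-like) throughout;
chromosome names carry the species as a prefix (``A_chr1``), which makes
species assignment of reads and genes testable without any alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import sparse

#: half-open genomic interval
Interval = tuple[int, int]

SPECIES = ("A", "B")

CATEGORIES = ("speciesA_cell", "speciesB_cell", "contaminated", "filtered", "empty")


def species_from_chrom(chrom: str) -> str:
    """Species tag encoded as the chromosome-name prefix (``A_...`` / ``B_...``)."""
    prefix = chrom.split("_", 1)[0]
    if prefix not in SPECIES:
        raise ValueError(f"chromosome {chrom!r} has no species prefix (expected 'A_' or 'B_')")
    return prefix


def _check_intervals(ivals: Sequence[Interval], what: str) -> None:
    prev_end = None
    for s, e in ivals:
        if not s < e:
            raise ValueError(f"{what}: empty or inverted interval [{s}, {e})")
        if prev_end is not None and s < prev_end:
            raise ValueError(f"{what}: intervals overlap or are unsorted at [{s}, {e})")
        prev_end = e


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered set of exons on its parent gene's chromosome."""

    transcript_id: str
    gene_id: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        _check_intervals(self.exons, f"transcript {self.transcript_id}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def junctions(self) -> tuple[Interval, ...]:
        """Donor/acceptor pairs of adjacent exons: (end of left exon, start of right)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing chromosome and strand."""

    gene_id: str
    species: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"gene {self.gene_id}: unknown species {self.species!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: needs at least one transcript")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} parent {t.gene_id} != {self.gene_id}"
                )

    @property
    def span(self) -> Interval:
        return (
            min(t.exons[0][0] for t in self.transcripts),
            max(t.exons[-1][1] for t in self.transcripts),
        )


class AnnotationSet:
    """Two-species gene annotation plus derived exon/junction indexes.

    The derived junction index contains exactly the donor/acceptor pairs of
    adjacent exons of every transcript; it is the coordinate truth used by
    junction classification, and the span/exon trees drive region assignment.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @cached_property
    def junction_index(self) -> dict[tuple[str, int, int], set[str]]:
        """(chrom, donor, acceptor) -> gene ids of transcripts carrying that junction."""
        idx: dict[tuple[str, int, int], set[str]] = {}
        for g in self.genes:
            for t in g.transcripts:
                for d, a in t.junctions:
                    idx.setdefault((g.chrom, d, a), set()).add(g.gene_id)
        return idx

    @cached_property
    def gene_span_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            s, e = g.span
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
        return trees

    @cached_property
    def exon_union_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome merged exons of all transcripts of all genes."""
        trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            t = trees.setdefault(g.chrom, IntervalTree())
            for tr in g.transcripts:
                for s, e in tr.exons:
                    t.addi(s, e)
        for t in trees.values():
            t.merge_overlaps(strict=False)
        return trees

    def representative_transcript(self, gene_id: str) -> TranscriptModel:
        """Longest transcript of the gene (ties broken by transcript_id)."""
        return min(self._by_id[gene_id].transcripts, key=lambda t: (-t.length, t.transcript_id))

    @cached_property
    def exonic_union_lengths(self) -> dict[str, int]:
        """Per-gene length of the union of all isoforms' exons (bp)."""
        out: dict[str, int] = {}
        for g in self.genes:
            ivals = sorted(iv for tr in g.transcripts for iv in tr.exons)
            total, cur_s, cur_e = 0, *ivals[0]
            for s, e in ivals[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            out[g.gene_id] = total + (cur_e - cur_s)
        return out


@dataclass(frozen=True)
class ReadRecord:
    """One block-aligned barcoded read.

    ``blocks`` are the aligned segments in genome coordinates; a gap between
    consecutive blocks is a candidate splice junction. ``ambiguous`` marks
    reads that aligned to both genomes.
    """

    chrom: str
    blocks: tuple[Interval, ...]
    barcode: str
    read_id: str
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id}: no blocks")
        _check_intervals(self.blocks, f"read {self.read_id}")
        for i in range(len(self.blocks) - 1):
            if self.blocks[i + 1][0] - self.blocks[i][1] < 1:
                raise ValueError(f"read {self.read_id}: zero-length gap between blocks")

    @property
    def species_of_chrom(self) -> str:
        return species_from_chrom(self.chrom)

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class DropletMatrix:
    """Barcode x gene sparse count matrix with per-gene species labels."""

    barcodes: list[str]
    genes: list[tuple[str, str]]  # (gene_id, species)
    counts: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        for gid, sp in self.genes:
            if sp not in SPECIES:
                raise ValueError(f"gene {gid!r} lacks a valid species label: {sp!r}")
        self.counts.sum_duplicates()
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return [gid for gid, _ in self.genes]

    def totals(self) -> np.ndarray:
        """Total counts per barcode."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def species_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts on species-A genes, counts on species-B genes) per barcode."""
        mask_a = np.array([sp == "A" for _, sp in self.genes])
        tot_a = np.asarray(self.counts[:, mask_a].sum(axis=1)).ravel()
        tot_b = np.asarray(self.counts[:, ~mask_a].sum(axis=1)).ravel()
        return tot_a, tot_b
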