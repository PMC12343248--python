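"""Splice-junction extraction, classification and skipped-exon quantification.

A junction is the gap between consecutive alignment blocks of a read: the
donor is the end of the left block (0-based exclusive), the acceptor the
start of the right block. Junction matching against the annotation is
exact-coordinate — a 1-bp shift of an annotated junction makes it novel.

A skipped-exon (SE) event is an internal exon E of one isoform for which
another isoform of the same gene carries the junction joining E's flanking
exons directly. Inclusion support is the minimum of the two inclusion
junction counts (conservative, the standard combiner); the inclusion
proportion is inclusion / (inclusion + exclusion).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .types import AnnotationSet, Interval, ReadRecord

__all__ = [
    "JunctionRecord",
    "SEEvent",
    "SelectionCriteria",
    "extract_junctions",
    "classify_junctions",
    "detect_se_events",
    "quantify_se",
    "select_genes",
    "junction_concordance",
]


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    donor: int
    acceptor: int
    count: int
    status: str | None = None  # "annotated" | "novel"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")
        if self.count < 1:
            raise ValueError("junction count must be >= 1")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor, self.acceptor)


@dataclass(frozen=True)
class SEEvent:
    gene_id: str
    chrom: str
    skipped_exon: Interval
    inclusion_junctions: tuple[Interval, Interval]
    exclusion_junction: Interval
    inclusion_count: int | None = None
    exclusion_count: int | None = None
    inclusion_proportion: float | None = None


@dataclass(frozen=True)
class SelectionCriteria:
    """Gene-selection thresholds for single-cell splicing quantification."""

    require_se: bool = True
    min_type_proportion: float = 0.5  # strict >
    min_supporting_reads: int = 5  # >=
    min_tpm: float = 16.0  # strict >

    def __post_init__(self) -> None:
        if self.min_type_proportion <= 0 or self.min_supporting_reads <= 0 or self.min_tpm <= 0:
            raise ValueError("all selection thresholds must be positive")


def extract_junctions(reads: list[ReadRecord]) -> list[JunctionRecord]:
    """Aggregate every between-block gap of every read by coordinates."""
    counter: Counter[tuple[str, int, int]] = Counter()
    for r in reads:
        for i in range(len(r.blocks) - 1):
            counter[(r.chrom, r.blocks[i][1], r.blocks[i + 1][0])] += 1
    return [
        JunctionRecord(chrom, d, a, count)
        for (chrom, d, a), count in sorted(counter.items())
    ]


def classify_junctions(
    junctions: list[JunctionRecord], annotation: AnnotationSet
) -> list[JunctionRecord]:
    """Set status and gene assignment against the annotation.

    Annotated iff (chrom, donor, acceptor) is an adjacent-exon pair of some
    transcript. Unannotated junctions are assigned to a gene when both
    endpoints fall within exactly one gene's span, else left unassigned.
    """
    idx = annotation.junction_index
    spans = annotation.gene_span_trees
    out: list[JunctionRecord] = []
    for j in junctions:
        genes = idx.get((j.chrom, j.donor, j.acceptor))
        if genes:
            out.append(replace(j, status="annotated", gene_id=min(genes)))
            continue
        tree = spans.get(j.chrom)
        containing = (
            sorted(
                iv.data
                for iv in tree.overlap(j.donor, j.acceptor)
                if iv.begin <= j.donor and j.acceptor <= iv.end
            )
            if tree is not None
            else []
        )
        gene_id = containing[0] if len(containing) == 1 else None
        out.append(replace(j, status="novel", gene_id=gene_id))
    return out


def detect_se_events(annotation: AnnotationSet) -> list[SEEvent]:
    """Enumerate skipped-exon event skeletons from the annotation alone."""
    events: list[SEEvent] = []
    seen: set[tuple[str, Interval, Interval]] = set()
    for gene in annotation:
        junction_sets = {
            t.transcript_id: set(t.junctions) for t in gene.transcripts
        }
        for t1 in gene.transcripts:
            for i in range(1, len(t1.exons) - 1):
                prev_e, exon, next_e = t1.exons[i - 1], t1.exons[i], t1.exons[i + 1]
                skip = (prev_e[1], next_e[0])
                if not any(
                    skip in js
                    for tid, js in junction_sets.items()
                    if tid != t1.transcript_id
                ):
                    continue
                key = (gene.gene_id, exon, skip)
                if key in seen:
                    continue
                seen.add(key)
                events.append(
                    SEEvent(
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        skipped_exon=exon,
                        inclusion_junctions=(
                            (prev_e[1], exon[0]),
                            (exon[1], next_e[0]),
                        ),
                        exclusion_junction=skip,
                    )
                )
    return events


def quantify_se(
    events: list[SEEvent], junctions: list[JunctionRecord]
) -> list[SEEvent]:
    """Fill junction-support counts and inclusion proportions into events."""
    counts = {j.key: j.count for j in junctions}
    out: list[SEEvent] = []
    for ev in events:
        (u_d, u_a), (d_d, d_a) = ev.inclusion_junctions
        inc = min(
            counts.get((ev.chrom, u_d, u_a), 0),
            counts.get((ev.chrom, d_d, d_a), 0),
        )
        exc = counts.get((ev.chrom, *ev.exclusion_junction), 0)
        prop = inc / (inc + exc) if inc + exc > 0 else None
        out.append(
            replace(
                ev,
                inclusion_count=inc,
                exclusion_count=exc,
                inclusion_proportion=prop,
            )
        )
    return out


def select_genes(
    gene_table: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> list[str]:
    """Apply the published gene-selection criteria.

    ``gene_table`` needs columns gene_id, has_SE, type_proportion,
    supporting_reads, tpm. Kept genes have an SE event (when required), a
    same-transcript-type proportion strictly above the threshold, at least
    ``min_supporting_reads`` supporting reads, and TPM strictly above
    ``min_tpm``.
    """
    keep = (
        (gene_table["type_proportion"] > criteria.min_type_proportion)
        & (gene_table["supporting_reads"] >= criteria.min_supporting_reads)
        & (gene_table["tpm"] > criteria.min_tpm)
    )
    if criteria.require_se:
        keep &= gene_table["has_SE"].astype(bool)
    return gene_table.loc[keep, "gene_id"].tolist()


def junction_concordance(
    set1: list[JunctionRecord], set2: list[JunctionRecord]
) -> pd.DataFrame:
    """Per-gene proportion of reference junctions recovered in set1.

    ``set2`` is the reference (e.g. bulk); its gene assignments define the
    gene universe. Returns columns gene_id, n_ref, n_shared, proportion.
    """
    keys1 = {j.key for j in set1}
    ref_by_gene: dict[str, set[tuple[str, int, int]]] = {}
    for j in set2:
        if j.gene_id is not None:
            ref_by_gene.setdefault(j.gene_id, set()).add(j.key)
    rows = []
    for gid in sorted(ref_by_gene):
        ref = ref_by_gene[gid]
        shared = len(ref & keys1)
        rows.append(
            {
                "gene_id": gid,
                "n_ref": len(ref),
                "n_shared": shared,
                "proportion": shared / len(ref),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_ref", "n_shared", "proportion"])
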