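"""Read-level filters applied before any quantification.

Two filters: removal of reads that aligned to both genomes, and removal of
PCR duplicates keyed on barcode plus alignment identity. With block-aligned
records and no simulated sequence, identical (chromosome, blocks) stands in
for identical sequence — exact for the simulator, where placement determines
sequence. ``ignore_barcode`` reproduces the bulk behaviour, where duplicates
are defined by sequence alone.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

from .types import Interval, ReadRecord

__all__ = ["DedupKey", "filter_ambiguous", "dedup_reads"]


class DedupKey(NamedTuple):
    """Two reads with equal keys are duplicates of one another."""

    barcode: str
    chrom: str
    blocks: tuple[Interval, ...]


def filter_ambiguous(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Drop reads flagged as mapping to both genomes; order preserved."""
    return [r for r in reads if not r.ambiguous]


def dedup_reads(
    reads: Iterable[ReadRecord], ignore_barcode: bool = False
) -> list[ReadRecord]:
    """Keep the first read seen per :class:`DedupKey`; order preserved.

    First-seen-wins makes the result deterministic without sorting, and the
    retained set is independent of how many duplicates each key has.
    """
    seen: set[DedupKey] = set()
    kept: list[ReadRecord] = []
    for r in reads:
        key = DedupKey("" if ignore_barcode else r.barcode, r.chrom, r.blocks)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept
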