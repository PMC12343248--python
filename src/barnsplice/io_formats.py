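"""Readers and writers for the formats the pipeline touches.

* GTF annotation (1-based closed on disk, converted to 0-based half-open).
* BED12 block-aligned reads. BED12 has no tag fields, so the barcode rides in
  the name column as ``BARCODE:READID`` and the score column carries the
  cross-genome ambiguity flag (0 = unique, 1 = ambiguous).
* MatrixMarket coordinate-integer count matrix plus ``barcodes.tsv`` and a
  two-column ``features.tsv`` (gene_id, species). The explicit species column
  takes precedence over the chromosome prefix.

Every reader/writer pair is a lossless round trip; writers emit canonical
lines so that read-then-write reproduces canonical input byte for byte.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy import io as spio
from scipy import sparse

from .types import (
    AnnotationSet,
    DropletMatrix,
    GeneModel,
    ReadRecord,
    SPECIES,
    TranscriptModel,
    species_from_chrom,
)


class ParseError(ValueError):
    """Malformed line in an input file; message carries the line number."""


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> AnnotationSet:
    """Parse a GTF annotation into an :class:`AnnotationSet`.

    Only ``exon`` features define structure; ``gene``/``transcript`` lines are
    accepted and used for metadata cross-checks. Species comes from a
    ``species`` attribute when present, else from the chromosome prefix.
    """
    transcripts: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}
    order: list[str] = []  # gene ids in file order
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_str = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = _parse_attrs(attr_str)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            species = attrs.get("species") or chrom.split("_", 1)[0]
            if species not in SPECIES:
                raise ParseError(
                    f"{path}:{lineno}: cannot determine species for chrom {chrom!r}"
                )
            if gid not in gene_meta:
                gene_meta[gid] = {"chrom": chrom, "strand": strand, "species": species}
                order.append(gid)
            if feature == "exon":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ParseError(
                        f"{path}:{lineno}: exon without parent transcript_id"
                    )
                rec = transcripts.setdefault(tid, {"gene_id": gid, "exons": []})
                if rec["gene_id"] != gid:
                    raise ParseError(
                        f"{path}:{lineno}: transcript {tid} assigned to two genes"
                    )
                # GTF is 1-based closed; internal convention is 0-based half-open.
                rec["exons"].append((start_i - 1, end_i))

    genes: dict[str, list[TranscriptModel]] = {gid: [] for gid in order}
    for tid, rec in transcripts.items():
        exons = tuple(sorted(rec["exons"]))
        genes[rec["gene_id"]].append(TranscriptModel(tid, rec["gene_id"], exons))

    models = []
    for gid in order:
        if not genes[gid]:
            continue  # gene line without exons contributes nothing
        meta = gene_meta[gid]
        models.append(
            GeneModel(
                gene_id=gid,
                species=meta["species"],
                chrom=meta["chrom"],
                strand=meta["strand"],
                transcripts=sorted(genes[gid], key=lambda t: t.transcript_id),
            )
        )
    return AnnotationSet(models)


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Write the annotation as GTF (1-based closed coordinates)."""
    with open(path, "w", newline="\n") as fh:
        for g in annotation:
            s, e = g.span
            attrs = f'gene_id "{g.gene_id}"; species "{g.species}";'
            fh.write(
                f"{g.chrom}\tbarnsplice\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'species "{g.species}";'
                )
                fh.write(
                    f"{g.chrom}\tbarnsplice\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for xs, xe in t.exons:
                    fh.write(
                        f"{g.chrom}\tbarnsplice\texon\t{xs + 1}\t{xe}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )


def read_bed12(path: str | Path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a BED12 file.

    blockStarts/blockSizes are expanded into absolute half-open intervals;
    the name field is split once on ``:`` into barcode and read id.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED fields")
            chrom = fields[0]
            try:
                chrom_start = int(fields[1])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED field") from None
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount={block_count} does not match "
                    f"blockSizes/blockStarts lengths"
                )
            name = fields[3]
            if ":" not in name:
                raise ParseError(
                    f"{path}:{lineno}: name {name!r} is not 'BARCODE:READID'"
                )
            barcode, read_id = name.split(":", 1)
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            yield ReadRecord(
                chrom=chrom,
                blocks=blocks,
                barcode=barcode,
                read_id=read_id,
                ambiguous=fields[4] == "1",
            )


def write_bed12(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as canonical BED12 (strand '+', no trailing commas)."""
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            start, end = r.span
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            starts = ",".join(str(s - start) for s, e in r.blocks)
            score = "1" if r.ambiguous else "0"
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.barcode}:{r.read_id}\t{score}\t+\t"
                f"{start}\t{end}\t0\t{len(r.blocks)}\t{sizes}\t{starts}\n"
            )


def read_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> DropletMatrix:
    """Load a barcode x gene MatrixMarket triplet matrix with its TSV axes.

    Triplet entries that repeat a cell are summed; entries absent from the
    triplet list are zero.
    """
    mat = spio.mmread(str(matrix_path))
    barcodes = [ln.rstrip("\n") for ln in open(barcodes_path) if ln.strip()]
    genes: list[tuple[str, str]] = []
    for lineno, ln in enumerate(open(features_path), start=1):
        ln = ln.rstrip("\n")
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{features_path}:{lineno}: expected 'gene_id<TAB>species'"
            )
        genes.append((parts[0], parts[1]))
    if mat.shape != (len(barcodes), len(genes)):
        raise ParseError(
            f"matrix header {mat.shape} inconsistent with {len(barcodes)} barcodes "
            f"and {len(genes)} features"
        )
    return DropletMatrix(barcodes=barcodes, genes=genes, counts=sparse.csr_matrix(mat))


def write_mtx(
    matrix: DropletMatrix,
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Write the matrix as MatrixMarket coordinate integer plus axis TSVs."""
    spio.mmwrite(str(matrix_path), matrix.counts.tocoo(), field="integer")
    with open(barcodes_path, "w", newline="\n") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)
    with open(features_path, "w", newline="\n") as fh:
        fh.writelines(f"{gid}\t{sp}\n" for gid, sp in matrix.genes)
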