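"""End-to-end orchestration: simulate -> preprocess -> call -> profile ->
junctions -> quantify, as one reproducible run.

``run_all`` writes every stage's output as plain text (GTF / BED12 /
MatrixMarket / TSV / JSON) into the run directory together with the fully
resolved configuration, and returns a summary. Stage outputs are individually
re-runnable from the intermediate files; there is no hidden state. All data
outputs are byte-deterministic under the configured seed (the run log carries
timestamps and is excluded from that contract).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .cell_calling import CallingThresholds, calling_summary, calls_to_frame, classify_droplets
from .coverage_regions import gene_body_coverage, region_fractions
from .junctions_splicing import (
    SelectionCriteria,
    classify_junctions,
    detect_se_events,
    extract_junctions,
    junction_concordance,
    quantify_se,
)
from .quantify_correlate import correlate, gene_lengths, pseudo_bulk, tpm
from .read_processing import dedup_reads, filter_ambiguous
from .synthetic_data import SimulationConfig, simulate_annotation, simulate_droplets

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = logging.getLogger("barnsplice")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    n_bins: int = 100
    coverage_pseudocount: float = 1e-9
    log_pseudocount: float = 1.0

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "thresholds": dataclasses.asdict(self.thresholds),
            "criteria": dataclasses.asdict(self.criteria),
            "n_bins": self.n_bins,
            "coverage_pseudocount": self.coverage_pseudocount,
            "log_pseudocount": self.log_pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def _tuples(section: dict) -> dict:
            return {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }

        return cls(
            sim=SimulationConfig(**_tuples(d.get("sim", {}))),
            thresholds=CallingThresholds(**d.get("thresholds", {})),
            criteria=SelectionCriteria(**d.get("criteria", {})),
            n_bins=d.get("n_bins", 100),
            coverage_pseudocount=d.get("coverage_pseudocount", 1e-9),
            log_pseudocount=d.get("log_pseudocount", 1.0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format, lineterminator="\n")


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline into ``outdir``; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_all(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    ann = simulate_annotation(config.sim)
    io_formats.write_gtf(ann, out / "annotation.gtf")
    matrix, reads, truth = simulate_droplets(config.sim, ann)
    io_formats.write_bed12(reads, out / "reads.bed")
    io_formats.write_mtx(
        matrix, out / "matrix.mtx", out / "barcodes.tsv", out / "features.tsv"
    )
    _write_tsv(truth.droplets, out / "truth.tsv")
    if truth.reads is not None:
        _write_tsv(truth.reads, out / "read_truth.tsv")
    log.info("simulate: %d genes, %d droplets, %d reads", len(ann), len(matrix.barcodes), len(reads))
    return ann, matrix, reads, truth


@_stage("preprocess")
def _preprocess(reads, out: Path):
    unique_genome = filter_ambiguous(reads)
    log.info("preprocess: removed %d ambiguous reads", len(reads) - len(unique_genome))
    clean = dedup_reads(unique_genome)
    log.info("preprocess: removed %d duplicate reads", len(unique_genome) - len(clean))
    io_formats.write_bed12(clean, out / "clean.bed")
    return clean


@_stage("call")
def _call(matrix, thresholds, out: Path):
    calls = classify_droplets(matrix, thresholds)
    _write_tsv(calls_to_frame(calls), out / "calls.tsv")
    summary = calling_summary(calls)
    _write_tsv(summary, out / "calling_summary.tsv")
    log.info("call: %s", dict(zip(summary["category"], summary["n_droplets"])))
    return calls, summary


@_stage("coverage")
def _coverage(clean, ann, config: PipelineConfig, out: Path):
    profile = gene_body_coverage(
        clean, ann, n_bins=config.n_bins, pseudocount=config.coverage_pseudocount
    )
    _write_tsv(
        pd.DataFrame(
            {
                "bin": np.arange(1, profile.n_bins + 1),
                "raw_depth": profile.raw_depth,
                "normalized": profile.normalized,
            }
        ),
        out / "profile.tsv",
    )
    regions = region_fractions(clean, ann)
    _write_tsv(
        pd.DataFrame(
            {
                "region": ["exonic", "intronic", "intergenic"],
                "fraction": [regions.exonic, regions.intronic, regions.intergenic],
            }
        ),
        out / "regions.tsv",
    )
    return profile, regions


@_stage("junctions")
def _junctions(clean, ann, out: Path):
    junctions = classify_junctions(extract_junctions(clean), ann)
    _write_tsv(
        pd.DataFrame(
            {
                "chrom": [j.chrom for j in junctions],
                "donor": [j.donor for j in junctions],
                "acceptor": [j.acceptor for j in junctions],
                "count": [j.count for j in junctions],
                "status": [j.status for j in junctions],
                "gene_id": [j.gene_id or "" for j in junctions],
            }
        ),
        out / "junctions.tsv",
    )
    events = quantify_se(detect_se_events(ann), junctions)
    _write_tsv(
        pd.DataFrame(
            {
                "gene_id": [e.gene_id for e in events],
                "chrom": [e.chrom for e in events],
                "exon_start": [e.skipped_exon[0] for e in events],
                "exon_end": [e.skipped_exon[1] for e in events],
                "inclusion_count": [e.inclusion_count for e in events],
                "exclusion_count": [e.exclusion_count for e in events],
                "inclusion_proportion": [
                    "" if e.inclusion_proportion is None else round(e.inclusion_proportion, 6)
                    for e in events
                ],
            }
        ),
        out / "se_events.tsv",
    )
    log.info("junctions: %d distinct, %d SE events", len(junctions), len(events))
    return junctions, events


@_stage("quantify")
def _quantify(matrix, calls, ann, clean, junctions, config: PipelineConfig, out: Path):
    lengths = gene_lengths(ann)
    tpms = {}
    for species, category in (("A", "speciesA_cell"), ("B", "speciesB_cell")):
        counts = pseudo_bulk(matrix, calls, category)
        if counts.sum() == 0:
            log.warning("quantify: no counts for %s pseudo-bulk", category)
            continue
        vec = tpm(counts, lengths)
        tpms[species] = vec
        _write_tsv(
            pd.DataFrame({"gene_id": vec.index, "counts": counts.values, "tpm": vec.values}),
            out / f"tpm_{species}.tsv",
        )

    # replicate-style concordance: split each species' called cells into
    # halves and compare pseudo-replicate expression and junction sets
    corr_rows = []
    concordance = pd.DataFrame(columns=["gene_id", "n_ref", "n_shared", "proportion"])
    for species, category in (("A", "speciesA_cell"), ("B", "speciesB_cell")):
        cells = [c.barcode for c in calls if c.category == category]
        if len(cells) < 4:
            continue
        half1, half2 = set(cells[0::2]), set(cells[1::2])
        idx1 = [i for i, bc in enumerate(matrix.barcodes) if bc in half1]
        idx2 = [i for i, bc in enumerate(matrix.barcodes) if bc in half2]
        c1 = pd.Series(
            np.asarray(matrix.counts[idx1, :].sum(axis=0)).ravel(),
            index=pd.Index(matrix.gene_ids),
        )
        c2 = pd.Series(
            np.asarray(matrix.counts[idx2, :].sum(axis=0)).ravel(),
            index=pd.Index(matrix.gene_ids),
        )
        if c1.sum() == 0 or c2.sum() == 0:
            continue
        res = correlate(
            tpm(c1, lengths), tpm(c2, lengths), log_pseudocount=config.log_pseudocount
        )
        corr_rows.append(
            {"species": species, "r": res.r, "pvalue": res.pvalue, "n_genes": res.n}
        )
    if corr_rows:
        _write_tsv(pd.DataFrame(corr_rows), out / "correlation.tsv")

    # junction concordance of half1 vs half2 reads, species A cells
    cells_a = {c.barcode for c in calls if c.category == "speciesA_cell"}
    if len(cells_a) >= 4:
        ordered = sorted(cells_a)
        h1, h2 = set(ordered[0::2]), set(ordered[1::2])
        r1 = [r for r in clean if r.barcode in h1]
        r2 = [r for r in clean if r.barcode in h2]
        if r1 and r2:
            s1 = extract_junctions(r1)
            s2 = classify_junctions(extract_junctions(r2), ann)
            concordance = junction_concordance(s1, s2)
    _write_tsv(concordance, out / "concordance.tsv")
    return tpms, corr_rows, concordance


def run_summary(matrix, calls, summary_df, regions, concordance) -> dict:
    """Headline metrics: category counts, exonic fraction, genes per cell."""
    called = {c.barcode for c in calls if c.category in ("speciesA_cell", "speciesB_cell")}
    idx = [i for i, bc in enumerate(matrix.barcodes) if bc in called]
    genes_per_cell = (
        float(np.median(np.asarray((matrix.counts[idx, :] > 0).sum(axis=1)).ravel()))
        if idx
        else 0.0
    )
    return {
        "category_counts": dict(
            zip(summary_df["category"], (int(x) for x in summary_df["n_droplets"]))
        ),
        "exonic_fraction": regions.exonic,
        "median_genes_per_called_cell": genes_per_cell,
        "mean_junction_concordance": (
            float(concordance["proportion"].mean()) if len(concordance) else None
        ),
    }


def _run_all(config: PipelineConfig, out: Path) -> dict:
    config.to_yaml(out / "config.yaml")
    ann, matrix, reads, truth = _simulate(config, out)
    clean = _preprocess(reads, out)
    calls, summary_df = _call(matrix, config.thresholds, out)
    profile, regions = _coverage(clean, ann, config, out)
    junctions, events = _junctions(clean, ann, out)
    tpms, corr_rows, concordance = _quantify(
        matrix, calls, ann, clean, junctions, config, out
    )
    summary = run_summary(matrix, calls, summary_df, regions, concordance)
    summary["replicate_correlations"] = corr_rows
    with open(out / "summary.json", "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("done: %s", summary)
    return summary
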