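"""Two-species barnyard droplet simulator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a human-like ("A") and mouse-like ("B") annotation with multi-isoform
genes containing skipped exons; droplets that are pure cells, cross-species
doublets, ruptured ("contaminated") cells or ambient-only empties; per-droplet
counts mixed with a cross-droplet ambient pool; and block-aligned reads placed
along transcripts with a tunable 3' bias, spanning junctions where fragments
cross exon boundaries, plus PCR duplicates and a small fraction of
cross-genome-ambiguous reads.

Three independent RNG streams are derived from the configuration:

* the annotation stream and the expression-program stream hang off
  ``program_seed`` (defaults to ``seed``), so two configurations sharing
  ``program_seed`` simulate the same annotation and expression program;
* the noise stream (droplet totals, ambient draws, read placement, duplicates)
  hangs off ``seed``.

Identical configurations therefore give byte-identical outputs, while
replicate simulations of one program differ only in sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import AnnotationSet, GeneModel, Interval, ReadRecord, TranscriptModel

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "ConfigError",
    "simulate_annotation",
    "simulate_droplets",
    "simulate_reads_for_transcripts",
]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the barnyard simulation; defaults are the study conditions.

    Fractions are in [0, 1]; lengths in bp; counts are positive integers.
    ``three_prime_bias`` is the decay parameter lambda of the fragment-start
    density ``exp(-lambda * d / L)`` where ``d`` is the distance of the start
    from the transcript's 3' end and ``L`` the transcript length.
    """

    seed: int = 0
    program_seed: int | None = None  # annotation + expression program stream

    # annotation geometry
    n_genes_per_species: int = 60
    isoforms_per_gene: tuple[int, int] = (1, 3)
    frac_genes_with_se: float = 0.5
    exons_per_transcript: tuple[int, int] = (6, 10)
    exon_length: tuple[int, int] = (100, 250)
    skipped_exon_length: tuple[int, int] = (40, 100)  # < read_length: one read can span both inclusion junctions
    intron_length: tuple[int, int] = (200, 1500)
    intergenic_gap: tuple[int, int] = (2000, 5000)

    # expression
    program_sigma: float = 1.0  # lognormal sd of per-gene expression weights
    isoform_weights: tuple[float, ...] | None = None  # molecule-level; None = uniform

    # droplet composition
    n_cells_a: int = 500
    n_cells_b: int = 500
    doublet_rate: float = 0.05
    n_empty_droplets: int = 2000
    ambient_fraction: float = 0.02
    contaminated_cell_rate: float = 0.02
    contaminated_ambient_fraction: float = 0.6  # rupture model: soup dominates
    empty_total_fraction: float = 0.01  # empty totals ~1% of cell totals

    # depth / noise
    mean_counts_per_cell: int = 5000
    dispersion: float = 10.0  # NB overdispersion (variance = mu + mu^2/dispersion)
    three_prime_bias: float = 1.0
    read_length: int = 150
    ambiguous_read_rate: float = 0.01
    duplicate_rate: float = 0.1
    emit_reads: bool = True

    def __post_init__(self) -> None:
        for name in (
            "frac_genes_with_se",
            "doublet_rate",
            "ambient_fraction",
            "contaminated_cell_rate",
            "contaminated_ambient_fraction",
            "empty_total_fraction",
            "ambiguous_read_rate",
            "duplicate_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes_per_species", "n_cells_a", "n_cells_b",
                     "mean_counts_per_cell", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_empty_droplets < 0:
            raise ConfigError("n_empty_droplets must be >= 0")
        for name in ("isoforms_per_gene", "exons_per_transcript", "exon_length",
                     "skipped_exon_length", "intron_length", "intergenic_gap"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name}=({lo}, {hi}) is not a valid range")
        if self.dispersion <= 0 or self.program_sigma < 0 or self.three_prime_bias < 0:
            raise ConfigError("dispersion must be > 0; sigmas/lambda must be >= 0")
        if (
            self.frac_genes_with_se > 0
            and self.isoforms_per_gene[1] >= 2
            and self.exons_per_transcript[1] < 3
        ):
            raise ConfigError(
                "skipped-exon genes need at least 3 exons per transcript"
            )

    @property
    def resolved_program_seed(self) -> int:
        return self.seed if self.program_seed is None else self.program_seed


@dataclass
class SimTruth:
    """Ground truth of one simulation run: the acceptance surface.

    ``droplets`` has one row per barcode (barcode, true_category in
    {pureA, pureB, doublet, contaminated, empty}, true_ambient_fraction);
    ``reads`` one row per emitted read (read_id, barcode, gene_id,
    transcript_id, is_ambient, is_duplicate, is_ambiguous) or None when read
    emission was disabled.
    """

    droplets: pd.DataFrame
    reads: pd.DataFrame | None = None


def _ann_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([1, config.resolved_program_seed])


def _prog_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([2, config.resolved_program_seed])


def _noise_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([3, config.seed])


def simulate_annotation(config: SimulationConfig) -> AnnotationSet:
    """Generate the two-species annotation.

    Each species gets ``n_genes_per_species`` genes laid head to tail on one
    chromosome. Every gene's first transcript uses all exons; in a fraction
    ``frac_genes_with_se`` of multi-isoform genes the second transcript drops
    exactly one internal exon (a skipped-exon pair); any further isoforms are
    5'-truncations, which introduce no additional skip junctions.
    """
    rng = _ann_rng(config)
    iso_lo, iso_hi = config.isoforms_per_gene
    ex_lo, ex_hi = config.exons_per_transcript
    genes: list[GeneModel] = []
    for species in ("A", "B"):
        chrom = f"{species}_chr1"
        cursor = 0
        for i in range(config.n_genes_per_species):
            gid = f"{species}G{i + 1:04d}"
            cursor += int(rng.integers(*config.intergenic_gap, endpoint=True))
            n_iso = int(rng.integers(iso_lo, iso_hi, endpoint=True))
            n_ex = int(rng.integers(ex_lo, ex_hi, endpoint=True))
            has_se = n_iso >= 2 and n_ex >= 3 and rng.random() < config.frac_genes_with_se
            se_idx = int(rng.integers(1, n_ex - 1)) if has_se else -1
            exons: list[Interval] = []
            pos = cursor
            for j in range(n_ex):
                lo, hi = (
                    config.skipped_exon_length if j == se_idx else config.exon_length
                )
                elen = int(rng.integers(lo, hi, endpoint=True))
                exons.append((pos, pos + elen))
                pos += elen
                if j < n_ex - 1:
                    pos += int(rng.integers(*config.intron_length, endpoint=True))
            cursor = pos
            strand = "+" if rng.random() < 0.5 else "-"

            transcripts = [TranscriptModel(f"{gid}.t1", gid, tuple(exons))]
            next_t = 2
            if has_se:
                skipped = tuple(x for j, x in enumerate(exons) if j != se_idx)
                transcripts.append(TranscriptModel(f"{gid}.t{next_t}", gid, skipped))
                next_t += 1
            # remaining isoforms: drop a growing 5' prefix of exons
            k = 1
            while len(transcripts) < n_iso and k < n_ex:
                transcripts.append(
                    TranscriptModel(f"{gid}.t{next_t}", gid, tuple(exons[k:]))
                )
                next_t += 1
                k += 1
            genes.append(GeneModel(gid, species, chrom, strand, transcripts))
    return AnnotationSet(genes)


def _sample_starts(
    rng: np.random.Generator, length: int, frag: int, lam: float, size: int
) -> np.ndarray:
    """Fragment 5' starts in transcript coordinates, density ~ exp(lam*s/L)."""
    smax = length - frag  # inclusive upper bound
    if smax <= 0:
        return np.zeros(size, dtype=np.int64)
    if lam <= 0:
        return rng.integers(0, smax + 1, size=size)
    c = lam / length
    u = rng.random(size)
    s = np.log1p(u * np.expm1(c * (smax + 1))) / c
    return np.minimum(s.astype(np.int64), smax)


def _transcript_layout(gene: GeneModel, t: TranscriptModel):
    """Exons in transcript (5'->3') order plus cumulative transcript offsets."""
    exs = t.exons if gene.strand == "+" else t.exons[::-1]
    cum = np.zeros(len(exs) + 1, dtype=np.int64)
    np.cumsum([e - s for s, e in exs], out=cum[1:])
    return exs, cum


def _fragment_blocks(
    exs: Sequence[Interval], cum: np.ndarray, strand: str, s: int, e: int
) -> tuple[Interval, ...]:
    """Map transcript-coordinate fragment [s, e) onto genomic blocks."""
    i = int(np.searchsorted(cum, s, side="right")) - 1
    pieces: list[Interval] = []
    while s < e:
        gs, ge = exs[i]
        off = s - int(cum[i])
        take = min(e - s, (ge - gs) - off)
        if strand == "+":
            pieces.append((gs + off, gs + off + take))
        else:
            pieces.append((ge - off - take, ge - off))
        s += take
        i += 1
    pieces.sort()
    return tuple(pieces)


def _isoform_read_weights(
    gene: GeneModel, molecule_weights: tuple[float, ...] | None
) -> np.ndarray:
    """Per-isoform read propensity: molecule abundance x transcript length.

    Fragmentation-based library chemistry yields reads proportional to the
    bases present, so a transcript's read share scales with its length as
    well as its molar abundance (the reason TPM length-normalizes).
    """
    n = len(gene.transcripts)
    if molecule_weights is None:
        mol = np.ones(n)
    else:
        mol = np.asarray(molecule_weights[:n], dtype=float)
        if len(mol) < n or mol.sum() <= 0:
            mol = np.pad(mol, (0, n - len(mol)), constant_values=0.0)
            if mol.sum() <= 0:
                mol = np.ones(n)
    w = mol * np.array([t.length for t in gene.transcripts], dtype=float)
    return w / w.sum()


def simulate_reads_for_transcripts(
    annotation: AnnotationSet,
    transcript_counts: Mapping[str, int],
    rng: np.random.Generator,
    read_length: int = 150,
    three_prime_bias: float = 0.0,
    barcode: str = "SIM",
) -> list[ReadRecord]:
    """Emit reads for explicit per-transcript counts (targeted experiments).

    Deterministic given ``rng``; transcripts are processed in sorted id order.
    """
    by_tid = {
        t.transcript_id: (g, t) for g in annotation for t in g.transcripts
    }
    reads: list[ReadRecord] = []
    counter = 0
    for tid in sorted(transcript_counts):
        n = int(transcript_counts[tid])
        if n <= 0:
            continue
        gene, t = by_tid[tid]
        exs, cum = _transcript_layout(gene, t)
        frag = min(read_length, t.length)
        starts = _sample_starts(rng, t.length, frag, three_prime_bias, n)
        for s in starts:
            blocks = _fragment_blocks(exs, cum, gene.strand, int(s), int(s) + frag)
            reads.append(
                ReadRecord(gene.chrom, blocks, barcode, f"r{counter:08d}")
            )
            counter += 1
    return reads


def _droplet_composition(config: SimulationConfig, rng: np.random.Generator):
    """Categories, barcodes and per-droplet ambient fractions."""
    n_cells = config.n_cells_a + config.n_cells_b
    n_doub = int(round(config.doublet_rate * n_cells))
    if n_doub > min(config.n_cells_a, config.n_cells_b):
        raise ConfigError("doublet_rate too high for the cell counts")
    n_pure_a = config.n_cells_a - n_doub
    n_pure_b = config.n_cells_b - n_doub
    categories = (
        ["pureA"] * n_pure_a
        + ["pureB"] * n_pure_b
        + ["doublet"] * n_doub
        + ["empty"] * config.n_empty_droplets
    )
    ambient_f = np.full(len(categories), config.ambient_fraction)
    # rupture model: some pure cells carry an elevated ambient share
    n_pure = n_pure_a + n_pure_b
    ruptured = rng.random(n_pure) < config.contaminated_cell_rate
    for i in np.flatnonzero(ruptured):
        categories[i] = "contaminated"
        ambient_f[i] = config.contaminated_ambient_fraction
    ambient_f[np.array(categories) == "empty"] = 1.0
    barcodes = [f"BC{i:06d}" for i in range(len(categories))]
    return categories, barcodes, ambient_f, n_pure_a, n_pure_b, n_doub


def simulate_droplets(
    config: SimulationConfig, annotation: AnnotationSet
) -> tuple["DropletMatrix", list[ReadRecord], SimTruth]:
    """Simulate droplet counts, reads and ground truth.

    Per-droplet totals are negative-binomially dispersed around
    ``mean_counts_per_cell`` (empties around ``empty_total_fraction`` of it;
    doublets are the sum of two cell draws). Each droplet's counts are a
    mixture ``(1 - f) * own_program + f * ambient_pool``, the ambient pool
    being the cell-number-weighted average of both species' programs (the
    soup of ruptured cells). When ``emit_reads`` is set, every count becomes
    one read placed on an isoform (propensity = molecule weight x length)
    with 3'-biased fragment starts; the returned matrix counts exactly the
    non-duplicate, non-ambiguous reads, mirroring the real preprocessing.
    """
    from .types import DropletMatrix  # local import avoids cycle at type-check time

    rng_prog = _prog_rng(config)
    rng = _noise_rng(config)

    gene_list = list(annotation)
    n_genes = len(gene_list)
    is_a = np.array([g.species == "A" for g in gene_list])

    # expression programs: lognormal weights per gene, normalized per species
    w = rng_prog.lognormal(mean=0.0, sigma=config.program_sigma, size=n_genes)
    prog_a = np.where(is_a, w, 0.0)
    prog_a /= prog_a.sum()
    prog_b = np.where(~is_a, w, 0.0)
    prog_b /= prog_b.sum()
    ambient = (config.n_cells_a * prog_a + config.n_cells_b * prog_b) / (
        config.n_cells_a + config.n_cells_b
    )

    categories, barcodes, ambient_f, n_pure_a, n_pure_b, n_doub = _droplet_composition(
        config, rng
    )
    n_drop = len(categories)
    cat_arr = np.array(categories)

    # totals: NB(mu, dispersion); doublets sum two cell draws
    r = config.dispersion
    mu_cell = float(config.mean_counts_per_cell)
    mu_empty = max(config.empty_total_fraction * mu_cell, 1.0)

    def nb(mu: float, size: int) -> np.ndarray:
        return rng.negative_binomial(r, r / (r + mu), size=size)

    totals = np.zeros(n_drop, dtype=np.int64)
    own = np.zeros((n_drop, n_genes))
    cells_mask = cat_arr != "empty"
    n_cells_total = int(cells_mask.sum())

    pure_a_like = (cat_arr == "pureA") | (
        (cat_arr == "contaminated") & (np.arange(n_drop) < n_pure_a)
    )
    pure_b_like = (cat_arr == "pureB") | (
        (cat_arr == "contaminated") & (np.arange(n_drop) >= n_pure_a) & cells_mask
    )
    totals[pure_a_like] = nb(mu_cell, int(pure_a_like.sum()))
    totals[pure_b_like] = nb(mu_cell, int(pure_b_like.sum()))
    own[pure_a_like] = prog_a
    own[pure_b_like] = prog_b

    doub_mask = cat_arr == "doublet"
    if n_doub:
        ta = nb(mu_cell, n_doub).astype(float)
        tb = nb(mu_cell, n_doub).astype(float)
        totals[doub_mask] = (ta + tb).astype(np.int64)
        mix = (ta[:, None] * prog_a[None, :] + tb[:, None] * prog_b[None, :]) / (
            ta + tb
        )[:, None]
        own[doub_mask] = mix

    empty_mask = cat_arr == "empty"
    if empty_mask.any():
        totals[empty_mask] = np.maximum(nb(mu_empty, int(empty_mask.sum())), 1)
        own[empty_mask] = ambient  # f = 1 anyway

    totals = np.maximum(totals, 1)

    # ambient / own split, then multinomial draws per component
    n_amb = rng.binomial(totals, ambient_f)
    n_own = totals - n_amb
    p_own = own / own.sum(axis=1, keepdims=True)
    own_counts = rng.multinomial(n_own, p_own)
    amb_counts = rng.multinomial(n_amb, ambient / ambient.sum())

    droplet_truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "true_category": categories,
            "true_ambient_fraction": ambient_f,
        }
    )

    if not config.emit_reads:
        counts = own_counts + amb_counts
        from scipy import sparse

        matrix = DropletMatrix(
            barcodes=barcodes,
            genes=[(g.gene_id, g.species) for g in gene_list],
            counts=sparse.csr_matrix(counts),
        )
        return matrix, [], SimTruth(droplets=droplet_truth)

    # ---- read emission ----------------------------------------------------
    reads: list[ReadRecord] = []
    truth_rows: dict[str, list] = {
        "read_id": [], "barcode": [], "gene_id": [], "transcript_id": [],
        "is_ambient": [], "is_duplicate": [], "is_ambiguous": [],
    }
    kept = np.zeros((n_drop, n_genes), dtype=np.int64)
    counter = 0
    lam = config.three_prime_bias
    drop_idx = np.arange(n_drop)

    for gi, gene in enumerate(gene_list):
        col_own = own_counts[:, gi]
        col_amb = amb_counts[:, gi]
        n_g = int(col_own.sum() + col_amb.sum())
        if n_g == 0:
            continue
        droplets_rep = np.concatenate(
            [np.repeat(drop_idx, col_own), np.repeat(drop_idx, col_amb)]
        )
        amb_flag = np.concatenate(
            [np.zeros(int(col_own.sum()), bool), np.ones(int(col_amb.sum()), bool)]
        )
        iso_w = _isoform_read_weights(gene, config.isoform_weights)
        tx_idx = rng.choice(len(gene.transcripts), size=n_g, p=iso_w)
        ambiguous = rng.random(n_g) < config.ambiguous_read_rate
        dup = rng.random(n_g) < config.duplicate_rate

        layouts = [_transcript_layout(gene, t) for t in gene.transcripts]
        starts = np.zeros(n_g, dtype=np.int64)
        frags = np.zeros(n_g, dtype=np.int64)
        for ti, t in enumerate(gene.transcripts):
            mask = tx_idx == ti
            k = int(mask.sum())
            if not k:
                continue
            frag = min(config.read_length, t.length)
            starts[mask] = _sample_starts(rng, t.length, frag, lam, k)
            frags[mask] = frag

        # distinct molecules in one droplet must not collide in placement
        # (flagged PCR duplicates are then the only identical copies); two
        # isoforms can yield the same blocks in shared exons, so the key is
        # the genomic block tuple itself
        used: dict[int, set[tuple[Interval, ...]]] = {}
        for j in range(n_g):
            d = int(droplets_rep[j])
            ti = int(tx_idx[j])
            t = gene.transcripts[ti]
            exs, cum = layouts[ti]
            taken = used.setdefault(d, set())
            blocks = _fragment_blocks(
                exs, cum, gene.strand, int(starts[j]), int(starts[j] + frags[j])
            )
            attempts = 0
            while blocks in taken and attempts < 20:
                starts[j] = _sample_starts(rng, t.length, int(frags[j]), lam, 1)[0]
                blocks = _fragment_blocks(
                    exs, cum, gene.strand, int(starts[j]), int(starts[j] + frags[j])
                )
                attempts += 1
            taken.add(blocks)
            rid = f"r{counter:08d}"
            amb_j = bool(ambiguous[j])
            reads.append(
                ReadRecord(gene.chrom, blocks, barcodes[d], rid, ambiguous=amb_j)
            )
            truth_rows["read_id"].append(rid)
            truth_rows["barcode"].append(barcodes[d])
            truth_rows["gene_id"].append(gene.gene_id)
            truth_rows["transcript_id"].append(t.transcript_id)
            truth_rows["is_ambient"].append(bool(amb_flag[j]))
            truth_rows["is_duplicate"].append(False)
            truth_rows["is_ambiguous"].append(amb_j)
            if not amb_j:
                kept[d, gi] += 1
            if dup[j]:
                # PCR duplicate: same placement and barcode, new read id
                drid = f"{rid}.dup"
                reads.append(
                    ReadRecord(gene.chrom, blocks, barcodes[d], drid, ambiguous=amb_j)
                )
                truth_rows["read_id"].append(drid)
                truth_rows["barcode"].append(barcodes[d])
                truth_rows["gene_id"].append(gene.gene_id)
                truth_rows["transcript_id"].append(t.transcript_id)
                truth_rows["is_ambient"].append(bool(amb_flag[j]))
                truth_rows["is_duplicate"].append(True)
                truth_rows["is_ambiguous"].append(amb_j)
            counter += 1

    from scipy import sparse

    matrix = DropletMatrix(
        barcodes=barcodes,
        genes=[(g.gene_id, g.species) for g in gene_list],
        counts=sparse.csr_matrix(kept),
    )
    truth = SimTruth(droplets=droplet_truth, reads=pd.DataFrame(truth_rows))
    return matrix, reads, truth
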