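"""Barnyard droplet calling.

Empty droplets are removed with a knee rule — one-tenth of the total counts
of the barcode at descending rank 100 — and the remaining droplets are
classified into five categories from their per-species counts:

1. species-A cell: counts on A genes exceed 1,000 and the fraction of
   cross-species (B) counts is below 0.25;
2. species-B cell: symmetric;
3. contaminated: cross-species fraction above 0.25 with total counts under
   30,000;
4. filtered: everything else (low-quality cells and doublets);
plus "empty" from the knee rule. All comparisons are strict inequalities as
written, so a droplet at exactly the 0.25 fraction satisfies neither a pure
rule nor the contamination rule and falls to "filtered". Cross-species
doublets typically land in "contaminated" or "filtered"; droplets where both
species exceed the count threshold additionally carry an ``is_likely_doublet``
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CATEGORIES, DropletMatrix

__all__ = [
    "CallingThresholds",
    "DropletCall",
    "empty_threshold",
    "classify_droplets",
    "calling_summary",
]


@dataclass(frozen=True)
class CallingThresholds:
    """Thresholds of the droplet-calling procedure (defaults as published)."""

    knee_rank: int = 100
    knee_divisor: float = 10.0
    min_species_counts: int = 1000
    cross_fraction_max: float = 0.25
    contaminated_total_max: int = 30000

    def __post_init__(self) -> None:
        if min(self.knee_rank, self.knee_divisor, self.min_species_counts,
               self.contaminated_total_max) <= 0:
            raise ValueError("all thresholds must be positive")
        if not 0.0 < self.cross_fraction_max < 1.0:
            raise ValueError("cross_fraction_max must be in (0, 1)")


@dataclass(frozen=True)
class DropletCall:
    barcode: str
    category: str
    total_counts: int
    counts_a: int
    counts_b: int
    cross_fraction: float
    is_likely_doublet: bool = False


def _ranked_totals(matrix: DropletMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Barcode order by descending totals, ties by barcode (1-based ranks)."""
    totals = matrix.totals()
    order = sorted(range(len(totals)), key=lambda i: (-totals[i], matrix.barcodes[i]))
    return totals, np.asarray(order)


def empty_threshold(
    matrix: DropletMatrix, thresholds: CallingThresholds = CallingThresholds()
) -> float:
    """Total-count threshold below or at which a droplet is called empty.

    T = (totals of the barcode at descending rank ``knee_rank``) / divisor.
    """
    totals, order = _ranked_totals(matrix)
    n_nonzero = int((totals > 0).sum())
    if n_nonzero < thresholds.knee_rank:
        raise ValueError(
            f"only {n_nonzero} barcodes with nonzero totals but knee_rank="
            f"{thresholds.knee_rank}; lower knee_rank for this dataset"
        )
    return float(totals[order[thresholds.knee_rank - 1]]) / thresholds.knee_divisor


def classify_droplets(
    matrix: DropletMatrix, thresholds: CallingThresholds = CallingThresholds()
) -> list[DropletCall]:
    """Assign every barcode exactly one of the five categories."""
    t = thresholds
    threshold = empty_threshold(matrix, t)
    totals = matrix.totals()
    counts_a, counts_b = matrix.species_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        cross = np.where(totals > 0, np.minimum(counts_a, counts_b) / np.maximum(totals, 1), 0.0)
        frac_a = np.where(totals > 0, counts_a / np.maximum(totals, 1), 0.0)
        frac_b = np.where(totals > 0, counts_b / np.maximum(totals, 1), 0.0)

    calls: list[DropletCall] = []
    for i, bc in enumerate(matrix.barcodes):
        tot = int(totals[i])
        ca, cb = int(counts_a[i]), int(counts_b[i])
        if tot <= threshold:
            cat = "empty"
        elif ca > t.min_species_counts and frac_b[i] < t.cross_fraction_max:
            cat = "speciesA_cell"
        elif cb > t.min_species_counts and frac_a[i] < t.cross_fraction_max:
            cat = "speciesB_cell"
        elif cross[i] > t.cross_fraction_max and tot < t.contaminated_total_max:
            cat = "contaminated"
        else:
            cat = "filtered"
        calls.append(
            DropletCall(
                barcode=bc,
                category=cat,
                total_counts=tot,
                counts_a=ca,
                counts_b=cb,
                cross_fraction=float(cross[i]),
                is_likely_doublet=ca > t.min_species_counts and cb > t.min_species_counts,
            )
        )
    return calls


def calling_summary(calls: list[DropletCall]) -> pd.DataFrame:
    """Per-category droplet counts and mean totals; counts sum to n barcodes."""
    if not calls:
        raise ValueError("no droplet calls to summarize")
    df = pd.DataFrame(
        {"category": [c.category for c in calls], "total": [c.total_counts for c in calls]}
    )
    out = (
        df.groupby("category")["total"]
        .agg(n_droplets="size", mean_counts="mean")
        .reindex(CATEGORIES)
    )
    out["n_droplets"] = out["n_droplets"].fillna(0).astype(int)
    out["mean_counts"] = out["mean_counts"].fillna(0.0)
    return out.reset_index()


def calls_to_frame(calls: list[DropletCall]) -> pd.DataFrame:
    """Tabular view of droplet calls (the calls.tsv schema)."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in calls],
            "category": [c.category for c in calls],
            "total": [c.total_counts for c in calls],
            "counts_A": [c.counts_a for c in calls],
            "counts_B": [c.counts_b for c in calls],
            "cross_fraction": [c.cross_fraction for c in calls],
            "is_likely_doublet": [c.is_likely_doublet for c in calls],
        }
    )
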