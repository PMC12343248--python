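"""TPM quantification, pseudo-bulk aggregation and cross-dataset correlation.

TPM (transcripts per million) length-normalizes read counts:
``rate_g = count_g / length_g``; ``tpm_g = 1e6 * rate_g / sum(rate)``. Gene
length is the exonic-union length over all isoforms. A TPM vector sums to
1e6 whenever any gene is expressed. Correlation between expression vectors
is Pearson's r on log10(TPM + 1), computed over the shared gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cell_calling import DropletCall
from .types import AnnotationSet, DropletMatrix

__all__ = ["tpm", "gene_lengths", "pseudo_bulk", "correlate", "CorrelationResult"]


def gene_lengths(annotation: AnnotationSet) -> pd.Series:
    """Exonic-union length per gene in bp (all isoforms merged)."""
    d = annotation.exonic_union_lengths
    return pd.Series(d, name="length").astype(np.int64)


def tpm(counts: pd.Series | Sequence[float], lengths: pd.Series | Sequence[float]) -> pd.Series:
    """Transcripts-per-million from per-gene counts and lengths.

    Inputs align on index when both are Series, else positionally. Raises on
    all-zero counts or non-positive lengths.
    """
    c = pd.Series(counts, dtype=float)
    l = pd.Series(lengths, dtype=float)
    if isinstance(counts, pd.Series) and isinstance(lengths, pd.Series):
        l = l.reindex(c.index)
        if l.isna().any():
            missing = list(c.index[l.isna()])[:3]
            raise ValueError(f"no length for genes {missing}")
    elif len(c) != len(l):
        raise ValueError("counts and lengths differ in length")
    if (l <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero counts: TPM undefined")
    rate = c.to_numpy() / l.to_numpy()
    return pd.Series(1e6 * rate / rate.sum(), index=c.index, name="tpm")


def pseudo_bulk(
    matrix: DropletMatrix, calls: list[DropletCall], category: str
) -> pd.Series:
    """Per-gene count sums over barcodes called as ``category``."""
    wanted = {c.barcode for c in calls if c.category == category}
    if not wanted:
        warnings.warn(f"no droplets called {category!r}; pseudo-bulk is all zero")
    rows = [i for i, bc in enumerate(matrix.barcodes) if bc in wanted]
    if rows:
        sums = np.asarray(matrix.counts[rows, :].sum(axis=0)).ravel()
    else:
        sums = np.zeros(len(matrix.genes), dtype=np.int64)
    return pd.Series(sums, index=pd.Index(matrix.gene_ids, name="gene_id"), name="counts")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    pvalue: float
    n: int


def correlate(
    expr1: pd.Series,
    expr2: pd.Series,
    log_pseudocount: float = 1.0,
    expressed_only: bool = False,
) -> CorrelationResult:
    """Pearson correlation of two TPM vectors after log10(x + pseudocount).

    Computed over the intersection of gene sets; ``expressed_only`` restricts
    to genes expressed in either dataset (double zeros dropped).
    """
    shared = expr1.index.intersection(expr2.index)
    a = expr1.loc[shared].to_numpy(dtype=float)
    b = expr2.loc[shared].to_numpy(dtype=float)
    if expressed_only:
        mask = (a > 0) | (b > 0)
        a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError(f"only {len(a)} shared genes; need at least 3")
    la, lb = np.log10(a + log_pseudocount), np.log10(b + log_pseudocount)
    r, p = stats.pearsonr(la, lb)
    return CorrelationResult(r=float(r), pvalue=float(p), n=len(a))
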