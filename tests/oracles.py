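"""Independent brute-force re-implementations used as oracles in tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops, direct transcription of the published rules.
"""

from __future__ import annotations


def naive_classify(barcodes, counts_a, counts_b, knee_rank=100, knee_divisor=10.0,
                   min_counts=1000, max_cross=0.25, contam_total=30000):
    """Naive droplet classification: sort, knee, then the four rules in order."""
    totals = [a + b for a, b in zip(counts_a, counts_b)]
    ranked = sorted(zip(totals, barcodes), key=lambda x: (-x[0], x[1]))
    threshold = ranked[knee_rank - 1][0] / knee_divisor
    out = []
    for bc, ca, cb in zip(barcodes, counts_a, counts_b):
        tot = ca + cb
        if tot <= threshold:
            out.append("empty")
        elif ca > min_counts and (cb / tot) < max_cross:
            out.append("speciesA_cell")
        elif cb > min_counts and (ca / tot) < max_cross:
            out.append("speciesB_cell")
        elif min(ca, cb) / tot > max_cross and tot < contam_total:
            out.append("contaminated")
        else:
            out.append("filtered")
    return out


def naive_region_label(blocks, exons, spans):
    """Label one read by per-base membership lists (exonic/intronic/intergenic)."""
    ex = intron = inter = 0
    for bs, be in blocks:
        for pos in range(bs, be):
            if any(s <= pos < e for s, e in exons):
                ex += 1
            elif any(s <= pos < e for s, e in spans):
                intron += 1
            else:
                inter += 1
    best = max(ex, intron, inter)
    for label, v in (("exonic", ex), ("intronic", intron), ("intergenic", inter)):
        if v == best:
            return label


def naive_junction_counts(reads):
    """Per-read gap scan, aggregated in a plain dict."""
    counts: dict[tuple[str, int, int], int] = {}
    for r in reads:
        for i in range(len(r.blocks) - 1):
            key = (r.chrom, r.blocks[i][1], r.blocks[i + 1][0])
            counts[key] = counts.get(key, 0) + 1
    return counts


def random_droplet_counts(rng, n):
    """Count pairs exercising all classification rules, with boundary cases."""
    kind = rng.integers(0, 6, size=n)
    ca = rng.integers(0, 40_000, size=n)
    cb = rng.integers(0, 40_000, size=n)
    ca[kind == 0] = rng.integers(1000, 30_000, size=(kind == 0).sum())
    cb[kind == 0] = rng.integers(0, 500, size=(kind == 0).sum())
    cb[kind == 1] = rng.integers(1000, 30_000, size=(kind == 1).sum())
    ca[kind == 1] = rng.integers(0, 500, size=(kind == 1).sum())
    ca[kind == 2] = rng.integers(0, 60, size=(kind == 2).sum())
    cb[kind == 2] = rng.integers(0, 60, size=(kind == 2).sum())
    # boundary cases: exact 0.25 fraction, exact 1000 counts, exact 30000 totals
    boundary = [(3000, 1000), (1000, 2999), (1000, 100), (22_500, 7_500),
                (24_000, 6_000), (15_000, 15_000)]
    for i, (a, b) in enumerate(boundary):
        if i < n:
            ca[i], cb[i] = a, b
    return ca.astype(int), cb.astype(int)
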