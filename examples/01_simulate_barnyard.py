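"""Simulate a small two-species barnyard experiment and inspect its truth.

The simulator produces an annotation (GTF-convertible), a barcode x gene
count matrix, block-aligned reads and per-droplet/per-read ground truth.
"""

from barnsplice import SimulationConfig, simulate_annotation, simulate_droplets

config = SimulationConfig(
    seed=1,
    n_genes_per_species=20,
    n_cells_a=30,
    n_cells_b=30,
    n_empty_droplets=100,
    mean_counts_per_cell=800,
)
annotation = simulate_annotation(config)
matrix, reads, truth = simulate_droplets(config, annotation)

print(f"genes: {len(annotation)}  droplets: {len(matrix.barcodes)}  reads: {len(reads)}")
print("droplet composition (ground truth):")
print(truth.droplets.true_category.value_counts().to_string())
kept = truth.reads[~truth.reads.is_duplicate & ~truth.reads.is_ambiguous]
print(f"matrix total {matrix.counts.sum()} == kept reads {len(kept)}")
# The matrix counts exactly the non-duplicate, non-ambiguous reads: the
# simulator's books balance, which is what makes it usable as ground truth.
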