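"""Run the whole pipeline (simulate -> preprocess -> call -> profile ->
junctions -> quantify) into one directory of plain-text outputs."""

from barnsplice import CallingThresholds, PipelineConfig, SimulationConfig, run_all

config = PipelineConfig(
    sim=SimulationConfig(
        seed=6, n_genes_per_species=15, n_cells_a=30, n_cells_b=30,
        n_empty_droplets=100, mean_counts_per_cell=1500,
    ),
    thresholds=CallingThresholds(knee_rank=40),  # small dataset: lower knee rank
)
summary = run_all(config, "example_run")
print("category counts:", summary["category_counts"])
print("exonic fraction:", round(summary["exonic_fraction"], 4))
print("median genes per called cell:", summary["median_genes_per_called_cell"])
# The run directory now holds annotation.gtf, reads.bed, the MatrixMarket
# matrix, calls.tsv, profile.tsv, junctions.tsv, se_events.tsv, TPM tables
# and summary.json; rerunning with the same config reproduces every file
# byte for byte.
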