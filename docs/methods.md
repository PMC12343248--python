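# Methods

This note records the models, parameter choices and numerical conventions
behind `barnsplice`, and what the simulator does and does not emulate.

## Coordinate and format conventions

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted at the IO boundary only. Species are tagged `A`
(human-like) and `B` (mouse-like); chromosome names carry the tag as a
prefix (`A_chr1`), and the features table of the count matrix carries an
explicit species column that takes precedence. BED12 has no tag fields, so
the cell barcode rides in the name column as `BARCODE:READID` and the score
column encodes the cross-genome-ambiguity flag (0 unique, 1 ambiguous).
Strand is taken from the annotation, never from reads: coverage and junction
logic are gene-body-oriented.

## Droplet calling

The empty threshold is *T* = (total counts of the barcode at descending
rank `knee_rank`)/`knee_divisor`, defaults 100 and 10. Rank is 1-based on
totals sorted descending with ties broken by barcode lexicographic order,
which makes the threshold deterministic. Having fewer nonzero barcodes than
`knee_rank` is an error (with the advice to lower `knee_rank`), never a
silent fallback: the rule is meaningless when rank 100 does not exist.

Classification applies the rules in order — species-A, species-B,
contaminated, filtered — with **strict** inequalities throughout. The two
pure rules and the contamination rule cannot conflict at the default 0.25
boundary (pure requires the cross fraction strictly below it, contamination
strictly above); a droplet at exactly 0.25 satisfies neither and falls to
"filtered". The "percentage of cross-species counts" is interpreted as
cross-species counts over *total* droplet counts, matching the axis
semantics of barnyard scatter plots. Doublets are not a primary category
(the procedure folds them into "filtered"/"contaminated"); droplets whose
counts exceed `min_species_counts` on *both* genomes additionally carry an
`is_likely_doublet` flag so the doublet vocabulary remains available.
Whether "exceeding 1,000" is strict is not decidable from the procedure's
wording; it is implemented strictly and exposed in `CallingThresholds`.

## Coverage and regions

Gene-body coverage uses the metagene convention: 100 bins (the RSeQC
default; configurable), representative transcript = longest per gene (ties
by transcript id). `raw_depth` is the per-bin **summed base coverage** over
genes, so its sum equals the total number of read bases overlapping
representative-transcript exons (a conservation property the tests check).
The normalized profile is mean-over-covered-genes, divided by total read
count, then log10 with pseudocount 1e-9 (configurable); the pseudocount
only guards empty bins and is far below any populated bin's value.

Region assignment is per read by majority of aligned bases with tie
precedence exonic > intronic > intergenic. "Intergenic" means outside every
gene's span; intronic is inside a span but outside the union of all
isoforms' exons.

## Junctions and skipped exons

Junction matching is exact-coordinate with no fuzz window: the simulator
emits exact donor/acceptor pairs, and alignment-level wobble correction is
out of scope. A skipped-exon event is an internal exon E of one isoform
such that another isoform of the same gene carries the junction joining E's
flanking exons directly; events are deduplicated on (gene, exon, exclusion
junction). Inclusion support is the minimum of the two inclusion-junction
counts — the conservative, standard combiner when no joint model is fitted —
and the inclusion proportion is inclusion/(inclusion+exclusion), reported
as missing when both are zero.

Gene selection uses four criteria: an SE event present, same-transcript-type
proportion strictly above 0.5, supporting reads ≥ 5, TPM strictly above 16.
The third criterion is worded in its source as an exclusion ("fewer than
5 reads") although it functions as an inclusion filter; it is implemented
as *at least* `min_supporting_reads` (default 5) required.

## TPM and correlation

Gene length for TPM is the exonic-union length over all isoforms
(configurable through `gene_lengths`). Correlation is Pearson's r on
log10(TPM + 1); the pseudocount 1 is the common choice for expression
scatter plots and is exposed. By default the correlation runs over all
shared genes including double zeros; an `expressed_only` flag restricts to
genes expressed in either dataset.

## The simulator

The generator emulates the statistical structure the analysis assumes, not
sequences: there is no FASTQ, no error model and no aligner. Reads are
emitted directly as block alignments, which is the level at which every
downstream operation works.

**Annotation.** Genes are laid head to tail per species with intergenic
gaps of 2–5 kb, 6–10 exons of 100–250 bp and introns of 0.2–1.5 kb —
transcripts of roughly 0.9–2.5 kb, in the range of typical mammalian mRNAs.
In skipped-exon genes the second isoform drops exactly one internal exon;
additional isoforms are 5′ truncations, which add no skip junctions.
Skipped exons are drawn at 40–100 bp, *shorter than the 150 bp read*, so a
single read can span both inclusion junctions; this makes the two inclusion
counts strongly correlated and the min-combiner nearly unbiased, i.e. the
event is properly observable at the junction level.

**Droplets.** Totals are negative-binomial around `mean_counts_per_cell`
(default 5 000) with dispersion 10 — per-cell library sizes in real droplet
data are overdispersed but concentrated within a cell type; dispersion 10
gives a coefficient of variation of ~0.32. Doublets merge one A and one B
cell (same-species doublets are invisible to the species rules and
therefore not modelled); `doublet_rate` = 0.05 of cells by default. The
ambient pool is the cell-number-weighted average of both species' programs,
the soup of ruptured cells; every droplet draws an `ambient_fraction`
(default 0.02) of its counts from it. A `contaminated_cell_rate` (default
0.02) of cells model in-droplet rupture with an elevated ambient share of
0.6 — enough that their cross-species fraction (~0.3) lands above the 0.25
classification boundary, which is what "contaminated" means operationally.
Empties are 100 % ambient with totals ~1 % of cell totals, so the rank-100
knee has a realizable gap. The source assay does not quantify its real
contamination rates; these defaults are plausible stand-ins and are all
configurable.

**Reads.** Each matrix count becomes one read. Within a gene, the isoform
is chosen proportional to molecule abundance × transcript length: in a
fragmentation-based (tagmentation) library, fragments per molecule scale
with length — the same fact that motivates TPM's length normalization.
Fragment starts follow density ∝ exp(−λ·d/L), d the start's distance from
the 3′ end, L the transcript length; λ defaults to 1 (the "slight 3′ bias"
such libraries show), and λ = 0 is exactly uniform. Fragments are
`read_length` (150 bp, PE150-like) in transcript coordinates and are mapped
through the exon structure, producing junction-spanning blocks. PCR
duplicates re-emit a read with a new id at `duplicate_rate` (default 0.1);
cross-genome-ambiguous reads are flagged at `ambiguous_read_rate` (default
0.01). Within one droplet, distinct molecules are rejection-sampled away
from placement collisions, so flagged duplicates are the *only* reads
sharing (barcode, chromosome, blocks) — this keeps the dedup operation's
semantics exact against the truth table. The returned matrix counts exactly
the non-duplicate, non-ambiguous reads, mirroring the real preprocessing
order.

**RNG streams.** Three independent `numpy` generators derive from the
configuration: annotation and expression program from `program_seed`
(default: `seed`), noise (totals, ambient, placement, duplicates) from
`seed`. Identical configurations give byte-identical outputs; two
configurations sharing `program_seed` are replicates of one experiment.

**What passing tests do not show.** The simulator has no sequence errors,
no alignment wobble around junctions, no UMIs (the assay is read-count
based), no same-species doublets, no gene-length/GC expression biases and
no batch structure. Results on it validate the *procedures* — thresholds,
bookkeeping, estimators — under the assumed noise model, not robustness to
real-data artefacts such as soft-clipped junction alignments or ambient
profiles that differ from the cell-average soup.

## Problem sizes

Matrix-level analyses (cell calling, empty threshold) run at full study
scale: 500+500 cells, thousands of empties, 5 000 mean counts per cell.
Read-level analyses use smaller, explicitly stated configurations — ~50 k
reads for junction conservation, 10 000 reads per gene for skipped-exon
recovery, ~20 k reads per λ for coverage bias, 200 k reads per replicate
for pseudo-bulk correlation, depth series 1 k/10 k/100 k for junction
concordance — sizes at which every estimator's sampling error is already
far inside its tolerance. The skipped-exon check reports the median
per-event inclusion proportion over the simulated SE genes against three
binomial standard errors at the median event's junction-read count; the
binomial *n* is the number of junction-spanning reads, since only those
inform the proportion.

## Known limitations

* Junction matching has no tolerance window; real aligners need one.
* The ambient pool is a single global profile; droplet-specific soup or
  distance-dependent contamination is not modelled.
* `select_genes`' "same transcript type proportion" is computed against
  whatever reference table the caller supplies; the package does not decide
  which external dataset defines transcript types.
* The pipeline's replicate correlation splits called cells into halves
  rather than simulating a second library; it demonstrates the estimator,
  not technical-replicate variance.
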