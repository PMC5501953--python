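# Methods

This note documents the models behind each stage of the toolkit, the
parameters that matter, the design choices made where several readings
were defensible, and what the synthetic-data generator does and does
not emulate.

## Chip and dispense model

A chip is an `n_rows × n_cols` grid of wells (default 72 × 72 = 5184,
150 nl each). Well barcodes (11-mers) are rejection-sampled uniformly
with a minimum pairwise Hamming distance of 3, so that perfect-match
demultiplexing is well posed: one sequencing error cannot convert one
valid barcode into another. Up to eight samples map to contiguous row
bands. Dispense follows limiting dilution: cells per well are i.i.d.
Poisson(λ) and each cell is live with probability `live_fraction`
(default 0.9). At λ = 1 the expected single-cell yield is
5184·e⁻¹ ≈ 1907 wells.

## Expression truth

`simulate_expression` draws a cells × genes matrix from a negative
binomial: gene baselines are log-normal, each cell type multiplies its
`markers_per_type` marker genes by `fold_change` (default 10), and
per-type means are scaled to an expected `depth` transcripts per cell.
The NB dispersion (variance = m + φm², default φ = 0.2) is typical of
UMI-count data; φ = 0 gives Poisson. Mitochondrial genes (name prefix
`mt-`) are calibrated per type so their expected library share equals
`mito_fraction` (default 6%, a typical value for healthy cultured
cells). Cell-type abundances are configurable; the islet benchmark uses
38/26/22/14%.

## Read emission and noise

Each true molecule receives a UMI uniform over 4¹⁰ **with
replacement** — collisions are possible and deliberately testable.
Because of that, an exact end-to-end identity (recovered counts ==
true counts) cannot hold at scale: at 50 cells × 200 genes × 2000
transcripts/cell, roughly a dozen same-(cell, gene) UMI pairs land
within Hamming distance ≤ 1 and merge. The generator therefore exposes
`collision_free_umis`, which rejects UMIs within distance 1 of an
existing UMI of the same (cell, gene); the identity tests enable it,
since they verify the pipeline, not UMI collision statistics.

PCR duplication is a per-molecule reads count (constant, shifted
Poisson, or geometric; default geometric with mean 4 — the paper-scale
regime of deep sequencing is not desk-reproducible, and mean 4 gives
the ≥ 2-read filter something to do). Substitution errors apply to the
barcode and cDNA at `base_error_rate` (default 0.5%, typical Illumina)
and to the UMI at `umi_error_rate`; UMI bases become N at `umi_n_rate`
(0.2%). Chimeric reads (default 1%) keep their UMI but draw their cDNA
from a random gene. Ambient RNA (default 2%) replaces a fraction of
each cell's molecules with draws from the pooled profile. Read 1 is
barcode + UMI padded to 25 bp with T (mirroring the oligo-dT context);
read 2 is a 50 bp window of the gene sequence, poly-A-filled when the
gene is shorter. The synthetic genome is one plus-strand interval per
gene on a single contig (genes 300 bp, spacers 100 bp), written as
minimal GTF (1-based closed; all internal coordinates are 0-based
half-open), which keeps gene assignment unambiguous. The SAM output
holds one record per pair keyed by the read-2 alignment, with CB/UB
tags for the sequenced barcode/UMI, NM for substitutions, and NH = 1.
Not emulated: realistic quality profiles, indels, isoforms, splicing,
multimapping, strand mixtures — so passing tests show pipeline
correctness under the stated noise processes, not robustness to
alignment artifacts.

## Image rendering and well selection

Fields cover 6 × 6 wells (16 px/well), so a full chip is 144 fields per
channel. Live cells are Gaussian blobs (σ = 1.3 px, amplitude 20 000 on
a 1000-count background) in channel 1; dead cells appear in both
channels. Noise is Gaussian with σ = amplitude/SNR. Cells within a well
sit on anchor positions (four corner points and the centre, ≥ 5 px
apart, ±0.25 px jitter) so that co-occupying cells resolve as separate
blobs at the default detection scale — real cells can clump, so
multi-cell detection on real images is harder than here.

Detection computes a scale-normalized LoG response (sign fixed so
bright blobs are positive; the truncated-kernel DC bias is subtracted
exactly, making constants map to zero). The auto threshold is
median + 5·MAD of the response, falling back to 5% of the peak above
the median on essentially noise-free fields; both are relative to the
data, so selection is invariant to affine intensity rescaling.
Connected components above threshold become objects; components below
`min_area` (4 px) are noise specks and dropped, while objects failing
`max_area` (400 px) or eccentricity (≤ 0.95, from second central
moments) are retained as debris. A well is selected iff it has exactly
one accepted channel-1 object, no channel-2 object (dead stain), and no
debris object. The dispense file lists selected wells with barcodes;
the Poisson summary reports the 0..4+ occupancy histogram and the MLE
λ̂ = mean object count.

## Demultiplexing

Barcode = read-1 bases 1–11, UMI = bases 12–21; bases 22–25 are
ignored. Assignment requires a perfect barcode match — no 1-mismatch
rescue, even though the distance-3 barcode design would permit it.
UMIs containing N pass through here and are excluded during
quantification, preserving the order of the filters. Conservation
holds: assigned + unassigned + too-short = total pairs.

## Quantification

Only uniquely mapping reads (NH = 1; a missing NH tag is a hard error)
are considered. A read is assigned to a gene iff its interval overlaps
exactly one gene under the strand policy (default sense; unstranded
available); overlaps of two genes are ambiguous and dropped. UMI
clustering semantics: connected components of the graph joining UMIs
with Hamming distance ≤ `umi_max_mismatch` (default 1). Directional
schemes exist, but components is the minimal reading of "cluster
similar UMIs", and the radius is config-switchable for comparison.
Cluster read support counts **all** member reads, so two 1-read UMIs at
distance 1 form a support-2 cluster that survives the ≥ 2-read
singleton filter — an interpretive choice documented here. A
consequence worth noting: transcript counts are monotone non-increasing
in `min_reads_per_umi` always, and monotone in `umi_max_mismatch` only
when the singleton filter is off (at `min_reads ≥ 2`, merging two
singletons can create a qualifying cluster and raise a count).
Clustering is implemented with wildcard-mask union-find (exact for
radius 1, O(n·L)); radius ≥ 2 falls back to pairwise comparison, and
both are verified against a brute-force connected-components oracle.

## QC, normalization, saturation

The six per-cell statistics: total reads, alignment rate (uniquely
mapped / total demultiplexed), mapped reads, total transcripts,
mitochondrial percentage (gene-name prefixes `mt-`/`MT-`), detected
genes (count ≥ 1). QC pass = total transcripts ≥ a per-dataset cutoff
chosen by inspection (no automated selection). Normalization:
factor(c) = total(c)/median(totals); every normalized total equals the
median raw total and re-normalization is the identity. Zero-total cells
are excluded with a warning. The saturation simulation samples, per
cell, a fraction d/D of gene-aligned reads (hypergeometric without
replacement by default — "a fraction of the existing reads"; Bernoulli
thinning optional) and re-runs clustering and the singleton filter
before recounting, then reports median detected genes/transcripts per
depth.

## Species mixing

Reads mapping to both genomes with ≤ 3 mismatches each are ambiguous
and excluded (boundary = excluded). The human cutoff is median +
5·IQR of human transcript counts among mouse-dominated cells
(symmetrically for mouse); quantiles use linear interpolation (type 7)
— the cutoffs are sensitive to the quantile rule, hence it is pinned.
Classification is strict (> cutoff); exceeding both cutoffs is a
multiplet, neither is unclassified; every cell gets exactly one label.
The overall multiplet rate is twice the cross-species percentage
(valid for a one-to-one mixture where half of random pairings are
same-species); the denominator is all mixture cells including
unclassified ones. The barnyard generator treats `doublet_rate` as the
probability a barcode holds a second cell whose species follows the
mixture proportions, so doubling the cross-species rate recovers it in
expectation.

## Clustering

Variable genes ranked by variance of log2(x+1)-normalized counts
(ties broken lexicographically; 500 genes for PCA, 100 for
heatmaps/clustering), computed on QC-passing cells. Transform =
log2(x+1) then per-gene mean centering. PCA is an exact SVD (no
randomized solver) with sign fixed by the largest-magnitude loading.
Hierarchical clustering uses 1 − Pearson correlation and average
linkage; constant-profile cells (undefined correlation) are removed
with a warning; the dendrogram cut k is user-set (4 for islets).
Clusters are labeled by the marker set with the highest mean normalized
expression; ties are "unresolved". Pairwise cell correlations support
transcript- and read-count modes; with dispersed PCR duplication the
transcript mode correlates more strongly, the UMI advantage.

## Dispenser QC (checkerboard)

One chip half holds no-template controls (2520 NTC wells); the other
alternates lambda-DNA Positives (1024) with negative Tests (1496).
"Signal" = Ct present and ≤ `max_ct` (default 35; the underlying assay
does not fix a cutoff, so it is config). The melt filter excludes
Test/NTC signal whose Tm is outside mean ± 3·SD (sample SD) of
Positive-well Tm. Misalignment % = %Test with signal − %NTC with
signal, reported unclamped (negative values are informative about
background asymmetry). The simulator plants misaligned contamination
(on-target melt) in Test wells, a symmetric in-window background
(cancelled by the subtraction), and off-target products at lower Tm
(removed by the melt filter).

## Pipeline

Stages run demux → quantify → QC from one YAML config with unknown-key
rejection and input existence checks before any compute. A JSON
manifest records per-stage parameter signatures, input checksums and
outputs; a stage is skipped when its signature still matches, so
re-running an identical config is a no-op. One global seed fans out to
per-stage sub-seeds via `SeedSequence` hashing of the stage name.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale sizes chosen to
make statistical checks decisive while keeping runs short: end-to-end
identity at 50 cells × 200 genes (~200 k read pairs), UMI-clustering
oracle equivalence over 1000 random instances (≤ 200 UMIs), barnyard
recovery at 499 cells × 50 replicate chips, clustering recovery at 468
cells, occupancy at the full 5184-well chip, dispenser QC over 50
chips. Statistical assertions use 3-SD bands derived from the planted
binomial/Poisson rates. Headline real-data figures of the modeled
platform (e.g. median pairwise r ≈ 0.83, ~2500 genes detected at 100 k
reads/cell, purity 97%/94%) depend on real sequencing libraries and are
covered here qualitatively by the corresponding simulation-recovery
properties, not reproduced numerically.

## Known limitations

- Gene models are single-interval, non-overlapping; the assigner
  handles overlapping genes conservatively (ambiguous → dropped) but
  assumes per-chromosome sorted non-overlapping intervals for the
  binary-search window.
- No alignment is performed; the simulator emits truth-derived
  alignments, so aligner-induced biases are out of scope.
- The image model has no PSF, vignetting, or debris morphology beyond
  the size/shape bounds; debris handling is a config-exposed stand-in
  for proprietary selection software.
- Same-species doublets are neither detected nor deconvolved; the 2×
  estimator assumes a balanced mixture.
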