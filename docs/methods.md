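# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `cistromix`. Coordinates are 0-based half-open (BED
convention) throughout; all readers and writers assume it.

## Coverage and occupancy model

A coverage track is a dense per-base vector per chromosome, suitable for the
toy genomes this package targets (tens of Mb); bedGraph input is expanded on
load and bases outside a track's extent read as zero. Read density follows
the shift-extend convention: each tag is lengthened by `extension_bp`
(default 200 bp, a fragment-length surrogate) in its 3′ direction — plus
strand grows past the end, minus strand past the start, clipped at the
chromosome origin — then per-base coverage is averaged over the query region
and divided by millions of mapped reads (rpm/bp). Extension in the 3′
direction, rather than resizing reads to a fixed length, is the standard
practice this package adopts; it is configurable.

Peak AUC is the plain per-base sum over the peak interval (signal·bp), which
makes it additive over any partition of the interval. Background
subtraction (whole-cell-extract track) is floored at zero: negative
occupancy is not meaningful, and the floor keeps promoter signals
non-negative and summable.

Gene-level promoter signal sums background-subtracted AUC over peaks whose
*summit* falls within ±2 kb of the TSS; distal signal uses summits within
1 Mb but outside the promoter window. Using the summit (midpoint when no
summit is called) as the peak's single representative point avoids
double-category edge cases for wide peaks; a whole-interval-overlap mode is
deliberately not the default. The same summit convention drives peak
classification (promoter within ±2 kb of a TSS; else enhancer on ≥1 bp
H3K27ac overlap; else other) so annotation and quantification agree.

## Statistics

* Distance-to-TSS distributions are compared with the two-sample
  Epps–Singleton characteristic-function test (valid under ties, unlike
  KS), evaluated at the standard t = (0.4, 0.8) points scaled by the pooled
  semi-interquartile range, with the small-sample covariance correction;
  samples under 5 observations are rejected.
* Multiple testing uses Benjamini–Hochberg step-up adjustment. Regulation
  classes follow strict `<` on FDR and inclusive `≤ / ≥` on the fold-change
  gate (down: FDR < 0.05 and log2FC ≤ −1; up: FDR < 0.05 and log2FC ≥ +1).
* Promoter-signal contrasts between regulation classes use two-sided
  Mann–Whitney U tests; empty groups skip the pair with a warning.
* The convenience fold change is log2((mean_KO + c)/(mean_control + c)) with
  pseudocount c = 0.01 RPKM, recorded in output metadata. Differential
  expression p-values are *inputs* (or simulated): count-model fitting is out
  of scope for this package.
* The leading-edge enrichment score is a weighted running sum over a ranked
  gene list: hits add |metric|^p normalized over set hits (p = 1 by default,
  p = 0 gives the unweighted statistic), misses subtract 1/(N−|S|); ES is the
  signed maximum deviation and the leading edge is the set members at or
  before the extremum (after it, for negative ES). If every hit's metric is
  zero the hit weights fall back to equal steps. An optional seeded
  permutation p-value (1000 set permutations) is provided; tie handling and
  the weight exponent are configurable because upstream conventions vary.

## Binned occupancy–expression trend

Expressed genes (≥1 RPKM in at least one sample) are sorted by promoter
signal descending, ties broken by gene id so the binning is input-order
invariant, and split into contiguous near-equal bins (when `n_genes mod
n_bins ≠ 0` the leading bins take one extra gene). Per-bin medians of signal
and log2FC form the trend; the package reports their Spearman correlation.
The same promoter-signal definition (background-subtracted AUC within ±2 kb)
is used here and in the class comparisons — one occupancy quantity
throughout.

## Accessibility dynamics

Consensus open-chromatin peaks are the union of both conditions' intervals
(≥1 bp overlap merges; touching intervals do not). Per-condition mean AUC is
recomputed on the shared consensus intervals from the replicate coverage
tracks, so both genotypes are measured on identical spans; without tracks a
degraded mode sums the member peaks' own AUCs. Ranks are ascending by mean
AUC within each condition, ties broken by genomic position. ATAC promoter
signal is the raw (not background-subtracted) AUC sum — there is no matched
input track for ATAC — and the gene ranking metric is
log2((control + 1)/(KO + 1)); the 1 signal·bp pseudocount guards silent
promoters. Because ranks are a permutation, strong rank losses at bound
promoters force a small compensatory rise elsewhere; "unchanged" for unbound
peaks therefore means small relative to the peak count, not exactly zero.

## Motif co-occurrence

"Correlation as a metric" is read as d = 1 − Pearson r on the binary hit
vectors (the phi coefficient), giving d ∈ [0, 2] with zero diagonal.
Clustering is agglomerative average linkage on the Euclidean distances
between rows of that distance matrix — the literal reading of clustering a
correlation-derived distance matrix "on Euclidean distance" — with direct
1 − r linkage available behind a flag; both recover the planted blocks in
tests. Factors are processed in lexicographic order so merge ties resolve
deterministically. Anchor association uses the per-factor 2×2 odds ratio
(hit × anchor-overlap) with the Haldane–Anscombe +0.5 correction applied to
all cells when any cell is zero.

## Synthetic epigenome

The generator writes a toy multi-assay dataset whose defaults are the study
conditions the pipeline is validated under:

* Genome: 8 chromosomes × 2 Mb; genes on a 6 kb grid starting 10 kb into
  each chromosome, with a gene desert at the chromosome end where distal
  peaks live (≥10 kb from any TSS, so planted promoter/distal classes map
  cleanly onto the ≤5 kb proximity readout).
* TF-A: 2000 peaks, an exact 70% planted at promoters (summit within ±500 bp
  of a TSS, one peak per bound gene); TF-B: 2000 peaks at 40%. Exact planted
  counts make the recovered fractions deterministic up to layout effects.
* Peak AUC = log-normal(μ=2, σ=0.5) height × uniform 200–600 bp width;
  background AUC = 10% of AUC with 10% relative noise. These values are
  chosen for a realistic dynamic range; nothing upstream prescribes them.
* Expression: planted log2FC = −β·q + N(0, σ) where q is the *quantile*
  (rank/n) of a bound gene's background-subtracted promoter signal among
  bound genes and q = 0 for unbound genes (β = 1, σ = 0.3 by default).
  Rank-normalizing the occupancy keeps the planted dose–response well spread
  over [0, 1]; normalizing by the maximum signal instead concentrates the
  effect near zero under the log-normal AUC model and washes out the binned
  trend, so the quantile form is the package's model of "decline
  proportional to occupancy". Indirect up-regulation (+1.2 to +2.5 log2
  units) is planted only at unbound genes. Replicate RPKMs carry 0.1 log2
  units of noise; per-gene p-values come from a two-sample t-test on log2
  RPKM across replicates (n = 2 per condition by default), keeping the
  FDR/classification machinery exercised without a count model. A 2% tail
  of sub-1-RPKM genes exercises the expression filter.
* ATAC: one open promoter per gene plus 300 desert regions; the knockout
  loses a fixed AUC fraction (0.5) only at TF-A-bound promoters. Replicate
  tracks are flat blocks (AUC/width over the interval), so track-based AUC
  recomputation is exact; TF and background tracks share a constant 0.02
  rpm/bp noise floor that cancels under background subtraction.
* Motifs: 500 open regions split into two anchor groups; a promoter-type
  factor block (KLF15/SP1/E2F4/ZFX) hits one group and a distal block
  (HNF4A/NR2F2/PPARA/PPARG) the other, with 5% Bernoulli flips.
* Determinism: one RNG stream per artifact, derived from the master seed by
  stable labels, so adding an output never perturbs existing ones; a fixed
  seed yields byte-identical file bundles.

A separate microarray stand-in (`simulate_microarray`) plants ~20 strongly
down-regulated genes among ~800, with a CBG-archetype gene at a 14-fold
decrease ranked 4th most down and 1–3 probes per gene, to exercise the
probe-averaging + fold-change-ranking + z-score recipe. It is synthetic: it
validates the recipe's machinery, not any deposited dataset.

What the generator does **not** emulate: read-level data (FASTQ), sequence
content and motif instances, realistic fragment-size or peak-shape models,
correlated replicate structure, mappability artifacts, or copy-number
effects. Passing the recovery tests therefore shows the pipeline's math and
bookkeeping are correct under the planted model, not that the biological
conclusions would survive real-data noise sources outside that model.

## Problem sizes and replicate counts

The validation suite runs the generator at 2000 peaks per factor for the
proximity contrast, 5000 genes / 100 bins for the occupancy–expression trend
(50 null replicates at β = 0), 500 genes per class for the direct/indirect
asymmetry, ~2300 consensus peaks with ~150 bound promoters for accessibility
dynamics, 500 regions × 8 factors for motif recovery, and ≥1000 null
replicates for test calibration — sizes at which the planted effects are
comfortably identified while the whole suite stays fast on one CPU.

## Known limitations

* Dense per-base tracks cap practical genome size at tens of Mb; a
  run-length in-memory representation would be needed beyond that.
* Promoter membership is summit-based; very broad peaks whose summit misses
  the window contribute nothing to a promoter even if they overlap it.
* The consensus-peak degraded mode (no tracks) sums member-peak AUCs, which
  double-counts conditions' overlapping evidence on merged intervals; prefer
  tracks.
* `epps_singleton_test` inherits its asymptotic p-value from the
  characteristic-function approximation; far-tail p-values (< 1e-300) are
  reported as 0.
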