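# cistromix

Promoter-centric integration of a transcription factor's cistrome with the
transcriptome and chromatin accessibility of its knockout.

## The problem

Some transcription factors act mainly as promoter-bound transactivators: they
sit within a couple of kilobases of transcription start sites (TSSs), keep the
local chromatin open, and drive expression of their direct targets, while
genes that go *up* when the factor is lost show no local binding at all —
their induction is indirect. Establishing that picture from genomics data
takes a specific chain of analyses: classify ChIP-seq peaks as promoter /
enhancer / other, compare distance-to-TSS distributions between factors,
quantify per-gene promoter occupancy, relate occupancy to knockout expression
changes, track how open-chromatin (ATAC-seq) peaks shift rank between
genotypes, and cluster motif co-occurrence over open chromatin. `cistromix`
implements that chain as a tested, reusable library plus CLI, together with a
seeded synthetic-epigenome generator that plants exactly this structure so
every stage can be validated against known ground truth. The archetype is a
liver transactivator (KLF15-like, ~70% of peaks promoter-proximal) contrasted
with an enhancer-biased factor (HNF4a-like, ~40%).

## Quantities computed

* **Read density** — reads are extended 200 bp in their 3′ direction, piled
  up per base, averaged over a region, and normalized to reads per million
  mapped reads per base pair (rpm/bp).
* **Peak AUC and promoter signal** — the AUC of a peak is the per-base sum of
  signal over its interval (signal·bp). A gene's promoter signal is
  Σ max(AUC − AUC_background, 0) over peaks whose summit lies within ±2 kb of
  its TSS; distal signal uses peaks within 1 Mb but outside the promoter.
* **Peak classes** — promoter if the summit is within ±2 kb of a TSS, else
  enhancer if the peak overlaps H3K27ac by ≥1 bp, else other. Distance
  distributions are compared with the two-sample Epps–Singleton test.
* **Differential expression interface** — genes below 1 RPKM in all samples
  are dropped; Benjamini–Hochberg FDR; a gene is *down* iff FDR < 0.05 and
  log2FC ≤ −1, *up* iff FDR < 0.05 and log2FC ≥ +1. Promoter-signal
  differences between classes use a two-sided Mann–Whitney U.
* **Occupancy–expression trend** — expressed genes are rank-ordered by
  promoter signal and split into n near-equal bins; per-bin medians of signal
  and log2FC give the waterfall trend.
* **Accessibility dynamics** — control and knockout ATAC peak sets are merged
  into consensus intervals, per-condition mean AUC (n = 2 replicates) is
  recomputed on the shared intervals, and peaks are ranked ascending by mean
  AUC per condition; rank shifts localize accessibility loss. Genes ranked by
  log2((ATAC_control + 1)/(ATAC_KO + 1)) feed a weighted running-sum
  leading-edge enrichment score ES ∈ [−1, 1] for a query gene set.
* **Motif co-occurrence** — factors are compared by d = 1 − r (Pearson phi on
  binary hit vectors over open-chromatin peaks) and hierarchically clustered
  (average linkage on Euclidean distances between rows of the distance
  matrix); per-factor odds ratios quantify association with anchor-factor
  overlap.

## Worked example

```python
from cistromix import (SimConfig, simulate, tss_proximal_fraction,
                       epps_singleton_test, distances_to_nearest_tss)
from cistromix.expression import (gene_signals, binned_occupancy_trend,
                                  log2_fold_change, filter_expressed)
from scipy.stats import spearmanr

bundle, truth = simulate(SimConfig(seed=1, make_tracks=False))
frac_a = tss_proximal_fraction(bundle.peaks_tf_a, bundle.genes, window=5000)
frac_b = tss_proximal_fraction(bundle.peaks_tf_b, bundle.genes, window=5000)
_, p = epps_singleton_test(
    distances_to_nearest_tss(bundle.peaks_tf_a, bundle.genes),
    distances_to_nearest_tss(bundle.peaks_tf_b, bundle.genes))
print(f"TF-A peaks within 5 kb of a TSS: {100*frac_a:.1f}%")
print(f"TF-B peaks within 5 kb of a TSS: {100*frac_b:.1f}%")
print(f"Epps-Singleton p: {p:.3g}")

table = filter_expressed(bundle.expression, bundle.control_columns + bundle.ko_columns)
sig = gene_signals(bundle.genes, bundle.peaks_tf_a).set_index("gene_id")
table = table.assign(
    signal=sig.loc[table["gene_id"], "promoter_signal"].to_numpy(),
    log2fc=log2_fold_change(table[bundle.ko_columns].mean(axis=1),
                            table[bundle.control_columns].mean(axis=1)))
trend = binned_occupancy_trend(table, n_bins=100)
rho = spearmanr(trend["median_signal"], trend["median_log2fc"]).statistic
print(f"Spearman(bin median occupancy, bin median log2FC): {rho:.3f}")
```

prints

```
TF-A peaks within 5 kb of a TSS: 70.0%
TF-B peaks within 5 kb of a TSS: 40.0%
Epps-Singleton p: 7.19e-85
Spearman(bin median occupancy, bin median log2FC): -0.971
```

i.e. the annotation stage recovers the planted 70% vs 40% promoter bias, the
two factors' distance-to-TSS distributions are sharply distinct, and genes
with more promoter occupancy lose proportionally more expression in the
knockout (strongly negative trend correlation).

The CLI mirrors the library stage by stage:

```sh
cistromix simulate --seed 1 --out-dir sim/
cistromix run --config run.yaml          # annotate -> integrate -> atac-rank -> enrich -> motif-cluster
cistromix annotate --peaks sim/peaks_tf_a.tsv --tss sim/tss.tsv \
    --h3k27ac sim/h3k27ac.bed --cpg sim/cpg_islands.bed --out anno.tsv
```

`cistromix run` writes per-stage TSVs, `summary.yaml`, and a `manifest.yaml`
recording every parameter, so a run is self-describing and reruns with the
same seed are byte-identical.

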