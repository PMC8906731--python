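"""ATAC-seq accessibility dynamics.

Builds a consensus open-chromatin peak set across two conditions, ranks
consensus peaks by mean AUC per condition (rank shifts reveal accessibility
loss in the knockout), quantifies per-gene promoter accessibility, and
computes a running-sum leading-edge enrichment score of a gene set within
an accessibility-change-ranked gene list.

ATAC promoter signal uses raw (not background-subtracted) peak AUC; there
is no matched background track for ATAC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .core import GenomicInterval, Peak, SignalTrack, peak_auc

ATAC_PSEUDOCOUNT = 1.0  # signal*bp, guards log2 ratios at silent promoters


@dataclass
class ConsensusPeak:
    interval: GenomicInterval
    mean_auc_control: float = 0.0
    mean_auc_ko: float = 0.0
    rank_control: int = 0
    rank_ko: int = 0
    anchor_tf_auc: float = 0.0

    @property
    def summit(self) -> int:
        return self.interval.midpoint


@dataclass
class EnrichmentResult:
    es: float
    leading_edge: list[str]
    running_sum: np.ndarray = field(repr=False)


def _union_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of overlapping (>= 1 bp) intervals, sort-and-sweep."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def merge_consensus(
    peaks_control: list[Peak],
    peaks_ko: list[Peak],
    tracks_control: list[SignalTrack] | None = None,
    tracks_ko: list[SignalTrack] | None = None,
    tf_track: SignalTrack | None = None,
) -> list[ConsensusPeak]:
    """Merge the two conditions' peak sets into consensus intervals.

    Overlapping intervals are unioned; per-condition mean AUC is then
    recomputed on the shared consensus interval from the condition's
    replicate tracks, so both conditions are measured on identical spans.
    Without tracks, the mean AUC falls back to the summed AUC of the
    condition's member peaks (documented degraded mode). ``tf_track``
    optionally attributes anchor-TF AUC to each consensus peak.
    """
    if not peaks_control and not peaks_ko:
        raise ValueError("cannot build a consensus from two empty peak sets")
    consensus = [
        ConsensusPeak(interval=iv)
        for iv in _union_intervals([p.interval for p in peaks_control + peaks_ko])
    ]
    if tracks_control is not None and tracks_ko is not None:
        for cp in consensus:
            cp.mean_auc_control = float(
                np.mean([peak_auc(t, cp.interval) for t in tracks_control])
            )
            cp.mean_auc_ko = float(np.mean([peak_auc(t, cp.interval) for t in tracks_ko]))
    else:
        for cp in consensus:
            cp.mean_auc_control = sum(
                p.auc for p in peaks_control if p.interval.overlaps(cp.interval)
            )
            cp.mean_auc_ko = sum(
                p.auc for p in peaks_ko if p.interval.overlaps(cp.interval)
            )
    if tf_track is not None:
        for cp in consensus:
            cp.anchor_tf_auc = peak_auc(tf_track, cp.interval)
    return consensus


def rank_peaks(consensus: list[ConsensusPeak]) -> list[ConsensusPeak]:
    """Assign ascending 1..n ranks by mean AUC within each condition.

    Ties break by (chrom, start) for determinism. Mutates and returns the
    input list.
    """
    n = len(consensus)
    for attr, rank_attr in (
        ("mean_auc_control", "rank_control"),
        ("mean_auc_ko", "rank_ko"),
    ):
        order = sorted(
            range(n),
            key=lambda i: (
                getattr(consensus[i], attr),
                consensus[i].interval.chrom,
                consensus[i].interval.start,
            ),
        )
        for rank, i in enumerate(order, start=1):
            setattr(consensus[i], rank_attr, rank)
    return consensus


def consensus_table(consensus: list[ConsensusPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in consensus],
            "start": [c.interval.start for c in consensus],
            "end": [c.interval.end for c in consensus],
            "mean_auc_control": [c.mean_auc_control for c in consensus],
            "mean_auc_ko": [c.mean_auc_ko for c in consensus],
            "rank_control": [c.rank_control for c in consensus],
            "rank_ko": [c.rank_ko for c in consensus],
            "anchor_tf_auc": [c.anchor_tf_auc for c in consensus],
        }
    )


def promoter_atac_signal(
    gene: GeneModel, atac_peaks: list[ConsensusPeak], window: int = 2000
) -> tuple[float, float]:
    """(control, KO) summed raw AUC of consensus peaks whose midpoint lies
    within ±``window`` of the gene's TSS."""
    if window < 0:
        raise ValueError("window must be >= 0")
    control = ko = 0.0
    for p in atac_peaks:
        if p.interval.chrom == gene.chrom and abs(p.summit - gene.tss) <= window:
            control += p.mean_auc_control
            ko += p.mean_auc_ko
    return control, ko


def gene_atac_signals(
    genes: list[GeneModel], atac_peaks: list[ConsensusPeak], window: int = 2000
) -> pd.DataFrame:
    rows = []
    for g in genes:
        c, k = promoter_atac_signal(g, atac_peaks, window)
        rows.append({"gene_id": g.gene_id, "atac_control": c, "atac_ko": k})
    return pd.DataFrame(rows)


def atac_rank_metric(
    control_signal, ko_signal, pseudocount: float = ATAC_PSEUDOCOUNT
) -> np.ndarray:
    """log2((control + c) / (KO + c)); larger means greater accessibility
    loss in the knockout."""
    c = np.asarray(control_signal, dtype=float)
    k = np.asarray(ko_signal, dtype=float)
    if np.any(c < 0) or np.any(k < 0):
        raise ValueError("signals must be >= 0")
    return np.log2((c + pseudocount) / (k + pseudocount))


def enrichment_score(
    ranked_genes: list[str],
    query_set: set[str],
    metric=None,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Weighted running-sum (leading-edge) enrichment of a gene set.

    Walking down the ranked list, the sum rises by |metric|^p (normalized
    over set hits) at each set member and falls by 1/(N - |S|) at each
    miss; the enrichment score is the signed maximum deviation from zero
    and the leading edge is the set members at or before that extremum
    (after it, for a negative score).
    """
    if not query_set:
        raise ValueError("query set is empty")
    n = len(ranked_genes)
    hits = np.array([g in query_set for g in ranked_genes])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("query set is disjoint from the ranked gene list")
    if n_hits == n:
        raise ValueError("query set covers the whole ranked list")
    if metric is None or weight_exponent == 0:
        weights = np.ones(n)
    else:
        weights = np.abs(np.asarray(metric, dtype=float)) ** weight_exponent
    hit_w = np.where(hits, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        total = float(n_hits)
    step = hit_w / total - (~hits) / (n - n_hits)
    running = np.cumsum(step)
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked_genes[: extremum + 1]) if hits[i]]
    else:
        leading = [g for i, g in enumerate(ranked_genes) if i >= extremum and hits[i]]
    return EnrichmentResult(es=es, leading_edge=leading, running_sum=running)


def enrichment_permutation_pvalue(
    ranked_genes: list[str],
    query_set: set[str],
    metric=None,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for the enrichment score (set labels
    shuffled over the ranked list)."""
    observed = enrichment_score(ranked_genes, query_set, metric, weight_exponent).es
    rng = np.random.default_rng(seed)
    names = list(ranked_genes)
    size = len(query_set & set(names))
    count = 0
    for _ in range(n_permutations):
        perm = set(rng.choice(names, size=size, replace=False))
        es = enrichment_score(names, perm, metric, weight_exponent).es
        if (es >= observed) if observed >= 0 else (es <= observed):
            count += 1
    return (count + 1) / (n_permutations + 1)
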