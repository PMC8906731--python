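"""Occupancy-expression integration.

Quantifies per-gene proximal (promoter) and distal TF occupancy as sums of
background-subtracted peak AUCs, relates occupancy to knockout expression
changes through rank-ordered binned trends, classifies differential
expression, and builds the display matrices (expression z-scores, occupancy
heatmaps/meta profiles) used to contrast directly activated genes with
indirectly up-regulated ones.

Differential-expression p-values are inputs (or simulated upstream): count
modelling is out of scope here. The convenience fold change is
log2((mean_KO + c) / (mean_control + c)) with pseudocount c = 0.01 RPKM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .core import Peak, SignalTrack, background_subtracted_auc

logger = logging.getLogger(__name__)

LOG2FC_PSEUDOCOUNT = 0.01  # RPKM


@dataclass
class GeneOccupancy:
    gene_id: str
    promoter_signal: float
    distal_signal: float


def filter_expressed(
    table: pd.DataFrame, sample_columns: list[str], min_rpkm: float = 1.0
) -> pd.DataFrame:
    """Drop genes with RPKM below ``min_rpkm`` in every sample."""
    if table.empty:
        raise ValueError("expression table is empty")
    keep = (table[sample_columns] >= min_rpkm).any(axis=1)
    return table.loc[keep].reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0)
    return stats.false_discovery_control(p, method="bh")


def log2_fold_change(
    mean_ko, mean_control, pseudocount: float = LOG2FC_PSEUDOCOUNT
) -> np.ndarray:
    return np.log2(
        (np.asarray(mean_ko, dtype=float) + pseudocount)
        / (np.asarray(mean_control, dtype=float) + pseudocount)
    )


def classify_regulation(
    log2fc, fdr, fc_threshold: float = 1.0, fdr_threshold: float = 0.05
):
    """down / up / ns labels: strict < on FDR, inclusive on the fold-change gate."""
    lfc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    q = np.atleast_1d(np.asarray(fdr, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("FDR values must lie in [0, 1]")
    out = np.full(lfc.shape, "ns", dtype=object)
    sig = q < fdr_threshold
    out[sig & (lfc <= -fc_threshold)] = "down"
    out[sig & (lfc >= fc_threshold)] = "up"
    return out if np.ndim(log2fc) else str(out[0])


def gene_promoter_signal(
    gene: GeneModel, peaks: list[Peak], window: int = 2000
) -> float:
    """Sum of background-subtracted AUC of peaks with summit within ±window of the TSS."""
    if window < 0:
        raise ValueError("window must be >= 0")
    total = 0.0
    for p in peaks:
        if p.chrom == gene.chrom and abs(p.summit - gene.tss) <= window:
            total += background_subtracted_auc(p)
    return total


def gene_distal_signal(
    gene: GeneModel,
    peaks: list[Peak],
    far_limit: int = 1_000_000,
    promoter_window: int = 2000,
) -> float:
    """Sum of background-subtracted AUC of peaks within ``far_limit`` of the TSS
    but outside the ±``promoter_window`` promoter region."""
    if far_limit <= promoter_window:
        raise ValueError("far_limit must exceed promoter_window")
    total = 0.0
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        d = abs(p.summit - gene.tss)
        if promoter_window < d <= far_limit:
            total += background_subtracted_auc(p)
    return total


def gene_signals(
    genes: list[GeneModel],
    peaks: list[Peak],
    promoter_window: int = 2000,
    far_limit: int = 1_000_000,
) -> pd.DataFrame:
    """Vectorized promoter and distal signal for every gene.

    Equivalent to calling gene_promoter_signal / gene_distal_signal per
    gene, but sweeps sorted summit arrays per chromosome.
    """
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.summit, background_subtracted_auc(p)))
    idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos = np.array([x[0] for x in pairs], dtype=np.int64)
        val = np.array([x[1] for x in pairs], dtype=float)
        idx[chrom] = (pos, np.concatenate(([0.0], np.cumsum(val))))
    prom = np.zeros(len(genes))
    dist = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g.chrom not in idx:
            continue
        pos, csum = idx[g.chrom]

        def window_sum(lo: int, hi: int) -> float:
            # inclusive window [lo, hi] on summit positions
            a = int(np.searchsorted(pos, lo, side="left"))
            b = int(np.searchsorted(pos, hi, side="right"))
            return float(csum[b] - csum[a])

        prom[i] = window_sum(g.tss - promoter_window, g.tss + promoter_window)
        dist[i] = window_sum(g.tss - far_limit, g.tss + far_limit) - prom[i]
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "promoter_signal": prom,
            "distal_signal": dist,
        }
    )


def binned_occupancy_trend(
    genes: pd.DataFrame,
    n_bins: int = 1000,
    signal_col: str = "signal",
    log2fc_col: str = "log2fc",
    gene_col: str = "gene_id",
) -> pd.DataFrame:
    """Rank genes by occupancy signal (descending) and report per-bin medians.

    Bins are contiguous and near-equal sized; when the gene count is not a
    multiple of ``n_bins`` the leading bins each take one extra gene. Ties
    in signal are broken by gene id so the binning is order-invariant.
    """
    n = len(genes)
    if n_bins < 1 or n_bins > n:
        raise ValueError(f"n_bins must be in [1, {n}], got {n_bins}")
    df = genes.sort_values(
        [signal_col, gene_col], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    edges = np.concatenate(([0], np.cumsum(sizes)))
    rows = []
    for b in range(n_bins):
        chunk = df.iloc[edges[b] : edges[b + 1]]
        rows.append(
            {
                "bin_index": b + 1,
                "median_signal": float(chunk[signal_col].median()),
                "median_log2fc": float(chunk[log2fc_col].median()),
                "n_genes": int(len(chunk)),
            }
        )
    return pd.DataFrame(rows)


def probe_average(probe_df: pd.DataFrame, gene_col: str = "gene_id") -> pd.DataFrame:
    """Average all probes for a gene (microarray convention) before analysis."""
    return probe_df.groupby(gene_col, sort=True).mean(numeric_only=True).reset_index()


def zscore_matrix(
    expression: pd.DataFrame,
    sample_columns: list[str],
    log2fc: pd.Series | None = None,
    top_k: int = 20,
    direction: str = "down",
    gene_col: str = "gene_id",
) -> pd.DataFrame:
    """Per-gene z-scores across samples for the top-k most regulated genes.

    Rows with multiple probes per gene are averaged first. z uses the sample
    (n-1) standard deviation; zero-variance genes yield a zero row with a
    logged warning. With ``log2fc`` given, genes are ranked ascending for
    ``direction='down'`` (most negative first) or descending for 'up';
    otherwise the input order is kept.
    """
    if len(sample_columns) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    df = probe_average(expression[[gene_col] + sample_columns], gene_col=gene_col)
    if log2fc is not None:
        order = log2fc.reindex(df[gene_col]).to_numpy()
        sel = np.argsort(order, kind="mergesort")
        if direction == "up":
            sel = sel[::-1]
        df = df.iloc[sel]
    df = df.head(top_k).set_index(gene_col)
    mat = df[sample_columns].to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("%d zero-variance gene(s) z-scored to all zeros", int(flat.sum()))
    sd[flat] = 1.0
    z = (mat - mean) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=df.index, columns=sample_columns)


def probe_average_fold_change_ranking(
    probe_df: pd.DataFrame,
    control_columns: list[str],
    ko_columns: list[str],
    gene_col: str = "gene_id",
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Probe-averaged expression with genes ranked by knockout/control fold change.

    The microarray re-analysis recipe: average probes per gene, compute
    log2(KO/control) on condition means, sort ascending so the most
    down-regulated genes lead.
    """
    df = probe_average(probe_df[[gene_col] + control_columns + ko_columns], gene_col)
    df["log2fc"] = log2_fold_change(
        df[ko_columns].mean(axis=1), df[control_columns].mean(axis=1), pseudocount
    )
    df = df.sort_values(["log2fc", gene_col], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def occupancy_matrix(
    anchors: list[tuple[str, int]],
    track: SignalTrack,
    flank: int = 5000,
    n_cols: int = 100,
    row_order: str = "by_region_sum",
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor-centred occupancy matrix plus the row order used.

    Each row is the per-column mean density over the ±``flank`` window split
    into ``n_cols`` near-equal bins; rows are sorted descending either by
    the central-column signal (``by_anchor_signal``) or the whole-row sum
    (``by_region_sum``). Column means of the matrix give the meta profile.
    Windows falling entirely off the chromosome produce zero rows.
    """
    if flank <= 0 or n_cols < 1:
        raise ValueError("flank must be > 0 and n_cols >= 1")
    from .core import GenomicInterval

    width = 2 * flank
    edges = np.linspace(0, width, n_cols + 1).astype(int)
    mat = np.zeros((len(anchors), n_cols))
    for i, (chrom, pos) in enumerate(anchors):
        window = GenomicInterval(chrom, max(pos - flank, 0), pos + flank) if pos + flank > 0 else None
        vals = np.zeros(width)
        if window is not None:
            got = track.values(window)
            vals[width - len(got) :] = got  # left-clip keeps the anchor centred
        for c in range(n_cols):
            seg = vals[edges[c] : edges[c + 1]]
            mat[i, c] = seg.mean() if len(seg) else 0.0
    if row_order == "by_anchor_signal":
        key = mat[:, n_cols // 2]
    elif row_order == "by_region_sum":
        key = mat.sum(axis=1)
    else:
        raise ValueError(f"unknown row_order {row_order!r}")
    order = np.argsort(-key, kind="mergesort")
    return mat[order], order


def meta_profile(matrix: np.ndarray) -> np.ndarray:
    """Column-wise mean of an occupancy matrix."""
    return matrix.mean(axis=0)


def signal_by_class_test(
    signals_by_class: dict[str, "np.ndarray | list[float]"],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U comparisons of promoter-signal groups.

    Defaults to (down, ns), (up, ns), (down, up). Pairs with an empty group
    are skipped with a warning.
    """
    if pairs is None:
        pairs = [("down", "ns"), ("up", "ns"), ("down", "up")]
    rows = []
    for a, b in pairs:
        ga = np.asarray(signals_by_class.get(a, []), dtype=float)
        gb = np.asarray(signals_by_class.get(b, []), dtype=float)
        if len(ga) == 0 or len(gb) == 0:
            logger.warning("skipping Mann-Whitney %s vs %s: empty group", a, b)
            continue
        u, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "u_statistic": float(u), "p_value": float(p)})
    return pd.DataFrame(rows)
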