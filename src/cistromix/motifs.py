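"""Motif co-occurrence clustering over open-chromatin regions.

Factors are compared by the correlation of their binary hit vectors across
open-chromatin peaks (for 0/1 vectors the Pearson r is the phi
coefficient); the pairwise distance is 1 - r. Hierarchical clustering is
then run on the Euclidean distances between rows of that correlation-
distance matrix (direct 1 - r linkage is available behind a flag), with
average linkage and lexicographic factor order for deterministic trees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


def factor_columns(matrix: pd.DataFrame) -> list[str]:
    """Motif columns of a hit matrix (anchor_* flag columns excluded)."""
    return [c for c in matrix.columns if not c.startswith("anchor_")]


def cooccurrence_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson correlation of factor hit vectors, in [0, 2]."""
    factors = factor_columns(matrix)
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    if len(matrix) < 3:
        raise ValueError("need at least 3 peaks")
    hits = matrix[factors].to_numpy(dtype=float)
    sd = hits.std(axis=0)
    flat = [f for f, s in zip(factors, sd) if s == 0]
    if flat:
        raise ValueError(f"zero-variance factor column(s): {flat}")
    dist = 1.0 - np.corrcoef(hits, rowvar=False)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=factors, columns=factors)


def cluster_motifs(
    distance: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    metric: str = "euclidean_rows",
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage agglomerative clustering of factors.

    ``metric='euclidean_rows'`` (default) clusters on Euclidean distances
    between rows of the correlation-distance matrix; ``'direct'`` uses the
    1 - r values themselves as the linkage dissimilarity. Returns cluster
    labels for the requested cut plus the scipy linkage (merge-tree) matrix.
    Factors are processed in lexicographic order so ties resolve
    deterministically.
    """
    factors = sorted(distance.columns)
    d = distance.loc[factors, factors]
    if n_clusters is not None and n_clusters > len(factors):
        raise ValueError(f"n_clusters {n_clusters} exceeds {len(factors)} factors")
    if metric == "euclidean_rows":
        condensed = pdist(d.to_numpy(), metric="euclidean")
    elif metric == "direct":
        condensed = squareform(d.to_numpy(), checks=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    tree = hierarchy.linkage(condensed, method="average")
    if n_clusters is not None:
        labels = hierarchy.fcluster(tree, t=n_clusters, criterion="maxclust")
    elif height is not None:
        labels = hierarchy.fcluster(tree, t=height, criterion="distance")
    else:
        raise ValueError("give n_clusters or height")
    return pd.Series(labels, index=factors, name="cluster"), tree


def merge_tree_table(tree: np.ndarray) -> pd.DataFrame:
    """Linkage matrix as a (child_a, child_b, height, size) table."""
    return pd.DataFrame(
        {
            "child_a": tree[:, 0].astype(int),
            "child_b": tree[:, 1].astype(int),
            "height": tree[:, 2],
            "n_members": tree[:, 3].astype(int),
        }
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (1 = identical up to relabeling)."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    if len(a) != len(b):
        raise ValueError("partitions must label the same items")
    n = len(a)
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def anchor_association(matrix: pd.DataFrame, anchor_col: str) -> pd.DataFrame:
    """Per-factor odds ratio of motif hits in anchor-overlapping peaks.

    From the 2x2 table (hit x anchor overlap); when any cell is zero the
    Haldane-Anscombe correction adds 0.5 to every cell.
    """
    if anchor_col not in matrix.columns:
        raise ValueError(f"missing anchor column {anchor_col!r}")
    anchor = matrix[anchor_col].to_numpy(dtype=bool)
    if anchor.all() or not anchor.any():
        raise ValueError("anchor overlap must split the peaks into two non-empty groups")
    rows = []
    for f in factor_columns(matrix):
        hit = matrix[f].to_numpy(dtype=bool)
        a = int(np.sum(hit & anchor))       # hit, anchor
        b = int(np.sum(hit & ~anchor))      # hit, no anchor
        c = int(np.sum(~hit & anchor))      # no hit, anchor
        d = int(np.sum(~hit & ~anchor))     # no hit, no anchor
        if min(a, b, c, d) == 0:
            a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a_, b_, c_, d_ = a, b, c, d
        rows.append(
            {
                "factor": f,
                "odds_ratio": (a_ * d_) / (b_ * c_),
                "n_hit_anchor": a,
                "n_hit_other": b,
                "n_nohit_anchor": c,
                "n_nohit_other": d,
            }
        )
    return pd.DataFrame(rows)
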