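"""Hierarchical clustering of chromosomes, clones and samples.

The order in which chromosomes are gained during leukemogenesis is
inferred from agglomerative clustering of per-cell gain vectors: Euclidean
distances between chromosome columns, complete linkage.  Chromosomes
separating from the remaining set at the largest merge heights sit at the
base of the dendrogram and are interpreted as the earliest gains (in
HHD-B-ALL typically 21, then 14 and X, with 4 and 6 acquired late).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

__all__ = [
    "DendrogramTree",
    "chromosome_linkage",
    "clone_clustering",
    "gain_order",
    "row_zscore",
]


@dataclass
class DendrogramTree:
    """Complete-linkage merge tree over labelled leaves.

    Wraps a scipy linkage matrix; merge heights are the complete-linkage
    Euclidean distances and are non-decreasing from leaves to root.
    """

    linkage: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing (complete linkage)")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> List[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (height at which two leaves
        first share a cluster)."""
        from scipy.cluster.hierarchy import cophenet

        return cophenet(self.linkage)

    def join_heights(self) -> Dict[str, float]:
        """Height of the merge in which each leaf participates as a
        singleton, i.e. the height at which it separates from everything
        else in the dendrogram."""
        n = self.n_leaves
        heights: Dict[str, float] = {}
        for row in self.linkage:
            a, b, h = int(row[0]), int(row[1]), float(row[2])
            for node in (a, b):
                if node < n:
                    heights[self.labels[node]] = h
        return heights

    def to_newick(self) -> str:
        """Newick export; branch lengths are merge-height differences."""
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def chromosome_linkage(
    gain_matrix: np.ndarray | pd.DataFrame,
    labels: Optional[Sequence[str]] = None,
) -> DendrogramTree:
    """Cluster panel chromosomes from a cells x chromosomes gain matrix.

    Distances are Euclidean between raw per-cell gain columns (pooled over
    the cohort), agglomerated by complete linkage.
    """
    if isinstance(gain_matrix, pd.DataFrame):
        labels = labels or [str(c) for c in gain_matrix.columns]
        X = gain_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(gain_matrix, dtype=float)
        labels = labels or [str(i) for i in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 chromosome columns to cluster")
    Z = sch.linkage(X.T, method="complete", metric="euclidean")
    return DendrogramTree(linkage=Z, labels=tuple(labels))


def row_zscore(matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Standardise rows to zero mean / unit variance (population SD).

    Constant rows become zero vectors; the boolean mask of such rows is
    returned alongside.
    """
    X = np.asarray(matrix, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # ddof=0, heatmap convention
    constant = (sd[:, 0] == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[constant, :] = 0.0
    return Z, constant


def clone_clustering(
    freq_matrix: pd.DataFrame,
) -> Tuple[DendrogramTree, DendrogramTree, pd.DataFrame]:
    """Cluster unique subclones (rows) and samples/groups (columns).

    Rows are z-score standardised before clustering (the heatmap row
    Z-score convention); both axes use complete-linkage Euclidean
    clustering.  Returns (row tree, column tree, standardised matrix).
    """
    X = freq_matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least a 2x2 clone-frequency matrix")
    Z, constant = row_zscore(X)
    if constant.all():
        raise ValueError("all clone rows are constant; nothing to cluster")
    zdf = pd.DataFrame(Z, index=freq_matrix.index, columns=freq_matrix.columns)
    row_tree = DendrogramTree(
        linkage=sch.linkage(Z, method="complete", metric="euclidean"),
        labels=tuple(str(i) for i in freq_matrix.index),
    )
    col_tree = DendrogramTree(
        linkage=sch.linkage(Z.T, method="complete", metric="euclidean"),
        labels=tuple(str(c) for c in freq_matrix.columns),
    )
    return row_tree, col_tree, zdf


def gain_order(tree: DendrogramTree) -> pd.DataFrame:
    """Rank chromosomes by acquisition order.

    A chromosome separating from the remaining set at a larger merge height
    is interpreted as an earlier gain (base of the tree).  Leaves joining at
    (numerically) equal heights share a rank.
    """
    heights = tree.join_heights()
    items = sorted(heights.items(), key=lambda kv: -kv[1])
    rows = []
    rank = 0
    prev_h = None
    for label, h in items:
        if prev_h is None or not np.isclose(h, prev_h):
            rank += 1
        rows.append((label, h, rank))
        prev_h = h
    return pd.DataFrame(rows, columns=["chromosome", "separation_height", "rank"])
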