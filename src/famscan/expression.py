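"""Expression-matrix processing: mean-ratio log2 normalization,
average-linkage hierarchical clustering, and expressed-tissue summaries.

The normalization reproduces the conventional heatmap preprocessing for
FPKM atlases: every value is divided by the grand mean of the matrix and
the ratios are log2-transformed, so the mean of the pre-log ratios is
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def normalize(matrix: pd.DataFrame, pseudocount: float = 0.01) -> pd.DataFrame:
    """log2 of (x + pseudocount) / grand mean of (x + pseudocount)."""
    if matrix.size == 0:
        raise ValueError("empty matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = matrix.astype(float) + pseudocount
    grand_mean = float(shifted.values.mean())
    if grand_mean == 0:
        raise ValueError("all-zero matrix with zero pseudocount")
    return np.log2(shifted / grand_mean)


@dataclass
class Dendrogram:
    """Average-linkage merge history over the matrix rows."""

    leaf_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaf_ids[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return {leaf: int(lab) for leaf, lab in zip(self.leaf_ids, labels)}

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6f}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.6f}"

        root = tree
        inner = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def hcluster(matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA (average linkage) on Euclidean row distances.

    Rows are clustered in their input order; scipy's agglomeration is
    deterministic for a given input, so sort rows by id upstream for an
    order-independent result.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    values = matrix.values.astype(float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in matrix")
    linkage = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    return Dendrogram(list(matrix.index), linkage)


def expressed_tissue_counts(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Number of conditions in which each gene reaches the expression
    threshold (FPKM units)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return (matrix >= threshold).sum(axis=1).astype(int)
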