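"""Design structure matrix: set x gene membership, Canberra-clustered.

The selected gene sets and genes are displayed as a binary membership
matrix whose rows (sets) and columns (genes) are ordered by
unsupervised agglomerative clustering (average linkage) on Canberra
distance.  On binary membership vectors the Canberra distance reduces
to the Hamming distance restricted to coordinates where not both
entries are zero, which groups sets sharing members and genes sharing
set assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import canberra as _canberra, pdist

from .simulate import GeneSetCatalog

__all__ = [
    "DesignStructureMatrix",
    "build_membership",
    "canberra_distance",
    "cluster_order",
    "order_dsm",
]


@dataclass
class DesignStructureMatrix:
    """Binary sets x genes membership with clustering metadata."""

    membership: pd.DataFrame
    row_order: list[str] | None = None
    col_order: list[str] | None = None
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    @property
    def ordered(self) -> pd.DataFrame:
        m = self.membership
        if self.row_order is not None:
            m = m.loc[self.row_order]
        if self.col_order is not None:
            m = m[self.col_order]
        return m


class EmptySelectionError(ValueError):
    pass


def build_membership(
    selected_sets: list[str],
    selected_genes: list[str],
    catalog: GeneSetCatalog,
) -> DesignStructureMatrix:
    """Binary membership matrix: entry (s, g) is 1 iff gene g is in set s."""
    if not selected_sets or not selected_genes:
        raise EmptySelectionError(
            "empty selection; relax set_q_max or gene_quantile_max"
        )
    data = np.zeros((len(selected_sets), len(selected_genes)), dtype=int)
    gene_pos = {g: j for j, g in enumerate(selected_genes)}
    for i, name in enumerate(selected_sets):
        for g in catalog.sets[name]:
            j = gene_pos.get(g)
            if j is not None:
                data[i, j] = 1
    return DesignStructureMatrix(
        membership=pd.DataFrame(data, index=selected_sets, columns=selected_genes)
    )


def canberra_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Canberra distance: sum |u_i - v_i| / (|u_i| + |v_i|), 0/0 -> 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(_canberra(u, v))


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order with deterministic tie rule.

    At each internal node the child subtree containing the smaller
    minimum original index is placed first.
    """
    if n == 1:
        return [0]

    leaves: dict[int, list[int]] = {}
    min_leaf: dict[int, int] = {}
    for i in range(n):
        leaves[i] = [i]
        min_leaf[i] = i
    for row_idx, (a, b, *_rest) in enumerate(Z):
        a, b = int(a), int(b)
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        node = n + row_idx
        leaves[node] = leaves[first] + leaves[second]
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
    return leaves[2 * n - 2]


def cluster_order(
    matrix: pd.DataFrame, axis: int = 0
) -> tuple[list, np.ndarray | None]:
    """Cluster one axis by Canberra distance; return (labels, linkage).

    Average-linkage agglomerative clustering; a single item yields the
    identity permutation with no linkage.
    """
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index if axis == 0 else matrix.columns)
    if axis == 1:
        data = data.T
    if len(labels) < 1:
        raise ValueError("axis has no items to cluster")
    if len(labels) == 1:
        return labels, None
    d = pdist(data, metric="canberra")
    Z = linkage(d, method="average")
    order = _leaf_order(Z, len(labels))
    return [labels[i] for i in order], Z


def order_dsm(dsm: DesignStructureMatrix) -> DesignStructureMatrix:
    """Fill in row/column orders of a membership matrix by clustering."""
    row_order, row_Z = cluster_order(dsm.membership, axis=0)
    col_order, col_Z = cluster_order(dsm.membership, axis=1)
    return DesignStructureMatrix(
        membership=dsm.membership,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
    )
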