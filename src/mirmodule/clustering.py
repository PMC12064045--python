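"""Ward hierarchical clustering of miRNA families by target-site profile.

Each seed family is represented by its row of site counts over the
module target genes; families with similar target repertoires merge
early.  Distances are Euclidean by default (correlation distance is
available), and agglomeration follows Ward's minimum-variance criterion
via the Lance-Williams recursion, so merge heights are monotone
non-decreasing.  Cutting the tree at a requested number of groups
yields the functional subgroups used to design multi-sponge constructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = ["profile_distance", "ward_cluster", "cut_clusters", "Dendrogram"]


def profile_distance(matrix, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric distance matrix between family site-count rows."""
    counts = getattr(matrix, "counts", matrix)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 families to compute distances")
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    x = counts.to_numpy(dtype=float)
    dist = squareform(pdist(x, metric=metric))
    return pd.DataFrame(dist, index=counts.index, columns=counts.index)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels.

    Merge i joins nodes ``Z[i, 0]`` and ``Z[i, 1]`` (ids < n are leaves)
    at height ``Z[i, 2]`` into new node ``n + i``.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows for n leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        """(left, right, height, new node id) per merge, in order."""
        n = self.n_leaves
        return [
            (int(row[0]), int(row[1]), float(row[2]), n + i)
            for i, row in enumerate(self.linkage)
        ]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, n_clusters: int) -> dict[str, int]:
        return cut_clusters(self, n_clusters)

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height increments."""
        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        subtree = {i: _quote_label(self.labels[i]) for i in range(n)}
        for left, right, height, new_id in self.merges:
            parts = []
            for child in (left, right):
                length = height - node_height[child]
                parts.append(f"{subtree.pop(child)}:{length:.6g}")
            subtree[new_id] = "(" + ",".join(parts) + ")"
            node_height[new_id] = height
        (root,) = subtree.values()
        return root + ";"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def ward_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Ward agglomeration of a symmetric distance matrix."""
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(arr, checks=False)
    z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(z, list(dist.index))


def cut_clusters(dendrogram: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Cut into exactly ``n_clusters`` groups; family -> cluster id.

    Cluster ids are 1-based and ordered by each cluster's
    lexicographically smallest member name, so the labelling is
    deterministic regardless of merge order.
    """
    n = dendrogram.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [1, {n}]")
    raw = hierarchy.fcluster(dendrogram.linkage, t=n_clusters, criterion="maxclust")
    members: dict[int, list[str]] = {}
    for label, cl in zip(dendrogram.labels, raw):
        members.setdefault(int(cl), []).append(label)
    if len(members) != n_clusters:
        raise RuntimeError(
            f"tree does not admit a cut into exactly {n_clusters} clusters"
        )
    order = sorted(members, key=lambda cl: min(members[cl]))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    return {
        label: relabel[int(cl)] for label, cl in zip(dendrogram.labels, raw)
    }
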