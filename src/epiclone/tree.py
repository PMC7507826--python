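"""Hierarchical clustering shared by clone and cell analyses.

Agglomerative clustering with Euclidean distance and complete linkage;
inputs are sorted lexicographically by label before linkage so ties break
deterministically and the result is invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .simulate import InputError


@dataclass
class Dendrogram:
    """Linkage result over labelled observations (rows of the profile)."""

    labels: list[str]  # lexicographic order used for linkage
    linkage_matrix: np.ndarray
    degenerate: bool  # all pairwise distances zero

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        return _linkage_to_newick(self.linkage_matrix, self.labels)


def hierarchical_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """Cluster the rows of ``profiles`` (observations × features).

    Constant (all-identical) profiles yield a degenerate dendrogram with
    zero merge heights rather than an error.
    """
    if profiles.shape[0] < 2:
        raise InputError("need at least 2 observations to cluster")
    ordered = profiles.sort_index(kind="stable")
    data = ordered.to_numpy(dtype=float)
    dists = pdist(data, metric="euclidean")
    z = linkage(dists, method="complete")
    return Dendrogram(
        labels=list(ordered.index),
        linkage_matrix=z,
        degenerate=bool(np.all(dists == 0)),
    )


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    # iterative post-order walk: cell-level trees can exceed the default
    # Python recursion limit
    n = len(labels)
    height = np.concatenate([np.zeros(n), z[:, 2]])
    rendered: dict[int, str] = {}
    stack = [n + z.shape[0] - 1]
    while stack:
        node = stack.pop()
        if node < n:
            rendered[node] = labels[node]
            continue
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        if left in rendered and right in rendered:
            parts = [
                f"{rendered[c]}:{height[node] - height[c]:.6g}" for c in (left, right)
            ]
            rendered[node] = f"({','.join(parts)})"
        else:
            stack.extend([node, left, right])
    return rendered[n + z.shape[0] - 1] + ";"
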