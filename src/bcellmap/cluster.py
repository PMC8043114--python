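"""Shared agglomerative-clustering helper (Euclidean, average linkage).

Used for the presence/absence population dendrogram, the z-score heatmap
orderings and the P/T-ratio population tree.  Items are sorted
lexicographically by label before linkage so that equal-distance merges
resolve the same way on every run and under input permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

__all__ = ["DendrogramResult", "average_linkage_tree", "root_split"]


@dataclass
class DendrogramResult:
    """Merge tree of an average-linkage clustering.

    ``labels`` is the (lexicographically sorted) item order the linkage
    ran on, ``leaf_order`` the dendrogram's left-to-right leaves,
    ``merge_heights`` the non-decreasing cophenetic merge distances, and
    ``tree`` a nested ``{"height", "children"}`` / ``{"label"}`` dict.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    merge_heights: list[float]
    tree: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"leaf_order": self.leaf_order, "tree": self.tree}, fh, indent=1)


def _nested(node, labels: list[str]) -> dict:
    if node.is_leaf():
        return {"label": labels[node.id]}
    return {
        "height": float(node.dist),
        "children": [_nested(node.left, labels), _nested(node.right, labels)],
    }


def average_linkage_tree(matrix: np.ndarray, labels: list[str]) -> DendrogramResult:
    """Cluster rows of ``matrix`` (Euclidean distance, average linkage)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != len(labels):
        raise ValueError("matrix rows must match labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    sorted_labels = [labels[i] for i in order]
    dists = pdist(matrix[order], metric="euclidean")
    z = linkage(dists, method="average")
    leaf_idx = leaves_list(z)
    tree = _nested(to_tree(z), sorted_labels)
    return DendrogramResult(
        labels=sorted_labels,
        linkage_matrix=z,
        leaf_order=[sorted_labels[i] for i in leaf_idx],
        merge_heights=[float(h) for h in z[:, 2]],
        tree=tree,
    )


def root_split(result: DendrogramResult) -> tuple[frozenset[str], frozenset[str]]:
    """Leaf sets of the two subtrees under the final merge."""

    def leaves(node: dict) -> frozenset[str]:
        if "label" in node:
            return frozenset([node["label"]])
        return frozenset().union(*(leaves(c) for c in node["children"]))

    left, right = result.tree["children"]
    return leaves(left), leaves(right)
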