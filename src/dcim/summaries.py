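"""Posterior pairwise probabilities and average-linkage dendrograms.

The marginal posteriors over partitions are summarised by the posterior
pairwise probability (PPP) of co-grouping: the proportion of retained Gibbs
sweeps in which two genes (or two samples) were grouped together.  Using
PPP as a similarity measure, agglomerative trees are built with unweighted
average linkage on the distance ``1 - PPP``; cutting a tree at height
``1 - p`` yields clusters whose average internal PPP exceeds ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PPPMatrix",
    "MergeTree",
    "ppp_from_counts",
    "average_linkage",
    "cut_all_levels",
    "extract_contexts",
]


@dataclass
class PPPMatrix:
    """Symmetric matrix of posterior pairwise co-grouping probabilities."""

    values: np.ndarray
    item_ids: list[str]
    n_kept: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PPP matrix must be square")
        if len(self.item_ids) != v.shape[0]:
            raise ValueError("item_ids length must match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("PPP matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PPP entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("PPP diagonal must be 1")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


@dataclass
class MergeTree:
    """Agglomerative dendrogram with heights on the 1 - PPP distance scale.

    Wraps a standard ``(n-1) x 4`` linkage matrix (as produced by
    ``scipy.cluster.hierarchy.linkage``) together with the leaf labels.
    """

    linkage_matrix: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        n = len(self.leaf_ids)
        if Z.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        if np.any(np.diff(Z[:, 2]) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")
        self.linkage_matrix = Z

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def ppp_from_counts(counts: np.ndarray, n_kept: int, item_ids: Sequence[str] | None = None) -> PPPMatrix:
    """Convert accumulated co-grouping counts into a PPP matrix.

    ``values = counts / n_kept``: the proportion of kept sweeps in which
    each pair of items was co-grouped.
    """
    counts = np.asarray(counts)
    if n_kept <= 0:
        raise ValueError("n_kept must be positive")
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if not np.array_equal(counts, counts.T):
        raise ValueError("counts must be symmetric")
    if not np.all(np.diag(counts) == n_kept):
        raise ValueError("count diagonal must equal n_kept")
    if counts.min() < 0 or counts.max() > n_kept:
        raise ValueError("counts must lie in [0, n_kept]")
    ids = list(item_ids) if item_ids is not None else [str(i) for i in range(counts.shape[0])]
    return PPPMatrix(values=counts / float(n_kept), item_ids=ids, n_kept=int(n_kept))


def average_linkage(ppp: PPPMatrix) -> MergeTree:
    """Unweighted average-linkage (UPGMA) tree on the distance 1 - PPP."""
    if ppp.n_items < 2:
        raise ValueError("need at least 2 items to build a tree")
    dist = 1.0 - ppp.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    Z = linkage(condensed, method="average")
    # numerical fuzz can leave tiny negative heights on all-ones PPP blocks
    Z[:, 2] = np.maximum.accumulate(np.clip(Z[:, 2], 0.0, None))
    return MergeTree(linkage_matrix=Z, leaf_ids=list(ppp.item_ids))


def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int64)
    seen: dict = {}
    for i, lab in enumerate(labels.tolist()):
        out[i] = seen.setdefault(lab, len(seen))
    return out


def cut_all_levels(tree: MergeTree) -> list[np.ndarray]:
    """Partitions from cutting the tree just below every distinct merge height.

    Returns one partition per achievable cluster count, from all singletons
    down to a single cluster, deduplicated when tied merge heights collapse
    adjacent levels.  Labels are contiguous 0-based integers in leaf order.
    """
    n = tree.n_leaves
    Z = tree.linkage_matrix
    partitions = [np.arange(n, dtype=np.int64)]
    for h in np.unique(Z[:, 2]):
        part = _relabel_first_occurrence(fcluster(Z, t=h, criterion="distance"))
        if not np.array_equal(part, partitions[-1]):
            partitions.append(part)
    return partitions


def extract_contexts(sample_tree: MergeTree, k: int = 2) -> np.ndarray:
    """The k-cluster cut of the sample tree, as contiguous 0-based labels.

    With tied merge heights fewer than k clusters may be achievable; the
    closest achievable count is returned (``fcluster`` maxclust semantics).
    """
    if not 1 <= k <= sample_tree.n_leaves:
        raise ValueError(f"k must be in 1..{sample_tree.n_leaves}")
    labels = fcluster(sample_tree.linkage_matrix, t=k, criterion="maxclust")
    return _relabel_first_occurrence(labels)
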