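"""Differential co-expression score (DCS) between two sample contexts.

Two genes are differentially co-expressed if they are co-clustered in one
context but not the other.  Given local PPP matrices ``P_c1`` and ``P_c2``
(posterior probabilities of local co-clustering within each context), the
per-gene score is built in four steps:

1. build an average-linkage tree per context from its local PPP matrix;
2. form the difference matrix ``Diff = |P_c1 - P_c2|``;
3. cut each tree at all levels and, for every resulting cluster ``g`` and
   gene ``i in g``, average ``Diff[i, j]`` over the co-members ``j``;
4. report each gene's maximum over all clusters from both trees.

Scores lie in [0, 1]: near 1 means the gene's co-clustering partners in
some tight cluster change almost completely between the two contexts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gibbs import ChainConfig, run_chain
from .model import Concentrations, ConjugatePrior, ExpressionMatrix
from .summaries import MergeTree, PPPMatrix, average_linkage, cut_all_levels, ppp_from_counts

__all__ = [
    "DCSResult",
    "local_ppp_per_context",
    "diff_matrix",
    "dcs_for_cluster",
    "dcs_genes",
    "overlap_significance",
]


@dataclass
class DCSResult:
    """Per-gene differential co-expression scores with their maximisers.

    ``table`` columns: ``gene_id``, ``score``, ``context`` (0 or 1, the
    context whose tree produced the maximising cluster), ``cluster_size``,
    ``rank`` (1 = highest score).  ``clusters[i]`` is the maximising
    cluster's member index array for gene i (empty when the score is 0).
    """

    table: pd.DataFrame
    clusters: list[np.ndarray]

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    @property
    def ranking(self) -> list[str]:
        """Gene ids ordered from highest to lowest score."""
        return self.table.sort_values("rank")["gene_id"].tolist()


def local_ppp_per_context(
    X: ExpressionMatrix,
    contexts: np.ndarray,
    config: ChainConfig | None = None,
    prior: ConjugatePrior | None = None,
    conc: Concentrations | None = None,
) -> tuple[PPPMatrix, ...]:
    """Local (within-context) gene PPP matrices from a fixed-context chain.

    Runs the Gibbs chain with the sample-to-context allocation pinned to
    ``contexts`` and, for each context ``r``, returns the matrix of
    proportions of kept sweeps in which two genes shared a local cluster
    within ``r``.
    """
    contexts = np.asarray(contexts)
    if len(contexts) != X.n_samples:
        raise ValueError("contexts must label every sample")
    labels, counts = np.unique(contexts, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every context needs at least 2 samples")
    base = config or ChainConfig()
    cfg = base.replace(fixed_contexts=contexts, track_local=True)
    summary = run_chain(X, cfg, prior=prior, conc=conc)
    return tuple(
        ppp_from_counts(c, summary.n_kept, X.gene_ids) for c in summary.co_local_counts
    )


def diff_matrix(p1: PPPMatrix, p2: PPPMatrix) -> np.ndarray:
    """Elementwise absolute difference of two local PPP matrices."""
    if p1.values.shape != p2.values.shape:
        raise ValueError("PPP matrices must have the same shape")
    if p1.item_ids != p2.item_ids:
        raise ValueError("PPP matrices must share the same gene order")
    return np.abs(p1.values - p2.values)


def dcs_for_cluster(i: int, members: np.ndarray, diff: np.ndarray) -> float:
    """Average absolute PPP difference between gene i and its co-members.

    ``sum_j diff[i, j] / (|g| - 1)`` over the other members j of cluster g
    when i is in g; 0 when i is not a member or g is a singleton.
    """
    members = np.asarray(members)
    if i not in members or len(members) < 2:
        return 0.0
    others = members[members != i]
    return float(diff[i, others].sum() / (len(members) - 1))


def _enumerate_clusters(tree: MergeTree) -> list[np.ndarray]:
    """Distinct non-singleton clusters appearing at any cut level."""
    seen: set[tuple[int, ...]] = set()
    out: list[np.ndarray] = []
    for part in cut_all_levels(tree):
        for lab in np.unique(part):
            members = np.flatnonzero(part == lab)
            if len(members) < 2:
                continue
            key = tuple(members.tolist())
            if key not in seen:
                seen.add(key)
                out.append(members)
    return out


def dcs_genes(p1: PPPMatrix, p2: PPPMatrix) -> DCSResult:
    """Per-gene DCS: the maximum cluster-average PPP difference.

    Builds an average-linkage tree per context, enumerates the clusters at
    every cut level of both trees, and takes each gene's maximum of
    :func:`dcs_for_cluster` over all (cluster, context) pairs.
    """
    diff = diff_matrix(p1, p2)
    n = diff.shape[0]
    best = np.zeros(n)
    best_ctx = np.zeros(n, dtype=np.int64)
    best_cluster: list[np.ndarray] = [np.array([], dtype=np.int64)] * n
    for ctx, ppp in enumerate((p1, p2)):
        for members in _enumerate_clusters(average_linkage(ppp)):
            sub = diff[np.ix_(members, members)]
            scores = sub.sum(axis=1) / (len(members) - 1)
            for pos, i in enumerate(members):
                if scores[pos] > best[i]:
                    best[i] = scores[pos]
                    best_ctx[i] = ctx
                    best_cluster[i] = members
    order = np.argsort(-best, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    table = pd.DataFrame(
        {
            "gene_id": p1.item_ids,
            "score": best,
            "context": best_ctx,
            "cluster_size": [len(c) for c in best_cluster],
            "rank": rank,
        }
    )
    return DCSResult(table=table, clusters=best_cluster)


def overlap_significance(
    list_a: set | list, list_b: set | list, universe: int
) -> tuple[float, float]:
    """Significance of the overlap of two gene lists from a common universe.

    Returns ``(log_odds, p)``: the log odds ratio of the 2x2 membership
    table (with Haldane's 0.5 correction when any cell is empty) and the
    hypergeometric upper-tail probability of an overlap at least as large
    as observed.
    """
    a, b = set(list_a), set(list_b)
    if universe < len(a | b):
        raise ValueError("universe smaller than the union of the lists")
    k = len(a & b)
    n_a, n_b = len(a), len(b)
    cells = np.array(
        [k, n_a - k, n_b - k, universe - n_a - n_b + k], dtype=float
    )
    if np.any(cells == 0):
        cells += 0.5
    log_odds = float(np.log(cells[0]) + np.log(cells[3]) - np.log(cells[1]) - np.log(cells[2]))
    p = float(hypergeom.sf(k - 1, universe, n_a, n_b))
    return log_odds, p
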