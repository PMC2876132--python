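"""Independent reference computations used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration, hand-rolled
agglomeration, direct order statistics — and shares no code with the
package paths it checks.
"""

import itertools
import math

import numpy as np
from scipy.special import gammaln

from dcim.model import nig_log_marginal


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def log_eppf(sizes, conc):
    """Log prior probability of a partition under a CRP/DP prior."""
    n = sum(sizes)
    return (
        len(sizes) * math.log(conc)
        + sum(gammaln(s) for s in sizes)
        + gammaln(conc)
        - gammaln(conc + n)
    )


def exact_cogrouping_posterior(X, prior, conc):
    """Exact posterior co-grouping probabilities by full enumeration.

    Sums over every (gene partition, sample partition, per-context local
    partition of the gene clusters) configuration; feasible only for a
    handful of genes and samples.  Returns (co_gene, co_sample) probability
    matrices.
    """
    N, M = X.shape
    co_gene = np.zeros((N, N))
    co_sample = np.zeros((M, M))
    terms = []
    total = -np.inf
    for gp in set_partitions(range(N)):
        lp_c = log_eppf([len(b) for b in gp], conc.alpha)
        Q = len(gp)
        for sp in set_partitions(range(M)):
            logw = lp_c + log_eppf([len(b) for b in sp], conc.beta)
            for ctx in sp:
                acc = -np.inf
                for lp in set_partitions(range(Q)):
                    w = log_eppf([len(b) for b in lp], conc.phi)
                    for t in lp:
                        gene_set = [g for q in t for g in gp[q]]
                        for j in ctx:
                            w += nig_log_marginal(
                                X[gene_set, j], prior.m0[j], prior.lam, prior.a, prior.tau
                            )
                    acc = np.logaddexp(acc, w)
                logw += acc
            terms.append((logw, gp, sp))
            total = np.logaddexp(total, logw)
    for logw, gp, sp in terms:
        w = math.exp(logw - total)
        for block in gp:
            for i, i2 in itertools.product(block, block):
                co_gene[i, i2] += w
        for block in sp:
            for j, j2 in itertools.product(block, block):
                co_sample[j, j2] += w
    return co_gene, co_sample


def naive_average_linkage(dist):
    """Textbook UPGMA agglomeration; returns the merge heights in order.

    Tie-break: the pair with the smallest distance, then lowest indices.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def percentile_order_statistic(values, q):
    """Linear-interpolation percentile computed directly from order stats."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    pos = (q / 100.0) * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
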