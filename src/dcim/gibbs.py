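"""Collapsed Gibbs sampler over the three allocation structures.

Each sweep resamples, in order: gene-to-global-cluster allocations ``C``,
global-to-local cluster allocations ``L`` within every context, and
sample-to-context allocations ``D`` (skipped when contexts are fixed).
Expression-pattern means and variances are integrated out analytically, so
every conditional is a Chinese-restaurant prior term times a closed-form
Normal-Inverse-Gamma marginal or predictive.

Sample moves need no statistic updates for other samples because every
(context, local cluster, sample) triple owns an independent pattern
dimension; the likelihood therefore factorises over sample columns given
``(C, L)``.

The "open a new context" move instantiates a small number of auxiliary
candidate contexts whose local clusterings are drawn from the CRP(phi)
prior over the current global clusters (the auxiliary-variable scheme for
non-conjugate components), keeping the chain's stationary distribution
exact.  The "open a new global cluster" move marginalises the new cluster's
local assignment in every context and then draws it from the exact
conditional.

Two interchangeable engines drive the gene sweep: a compiled kernel
(:mod:`dcim.kernels`, the default) and a vectorised numpy reference
implementation.  They share the bookkeeping and target the same posterior;
the reference engine exists for transparency and cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .model import (
    AllocationState,
    Concentrations,
    ConjugatePrior,
    ExpressionMatrix,
    nig_log_marginal_stats,
    nig_log_predictive_stats,
)

__all__ = ["ChainConfig", "ChainSummary", "initialize_state", "run_chain"]


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


@dataclass
class ChainConfig:
    """Settings for one Gibbs chain.

    ``n_keep`` is the number of retained draws; the chain performs
    ``n_burnin + n_keep * thin`` sweeps in total.  ``fixed_contexts`` pins
    the sample-to-context allocation (labels are canonicalised to 0-based,
    first-occurrence order) and disables the context update.
    ``prior_only`` drops all likelihood terms, so the chain samples the
    three CRP priors — useful for validating the allocation machinery.
    ``engine`` selects the gene-sweep implementation: ``"numba"``
    (compiled, default) or ``"numpy"`` (reference).  ``track_local``
    controls accumulation of within-context co-clustering counts; it
    defaults to on exactly when contexts are fixed.
    """

    n_burnin: int = 500
    n_keep: int = 2000
    thin: int = 1
    seed: int = 0
    resample_concentrations: bool = False
    fixed_contexts: Optional[np.ndarray] = None
    prior_only: bool = False
    n_aux_contexts: int = 4
    keep_draws: bool = False
    track_local: Optional[bool] = None
    engine: str = "numba"

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_keep < 1 or self.thin < 1:
            raise ValueError("need n_burnin >= 0, n_keep >= 1, thin >= 1")
        if self.n_aux_contexts < 1:
            raise ValueError("need at least one auxiliary context candidate")
        if self.engine not in ("numba", "numpy"):
            raise ValueError("engine must be 'numba' or 'numpy'")
        if self.fixed_contexts is not None:
            self.fixed_contexts = _canonical_labels(np.asarray(self.fixed_contexts))

    def replace(self, **overrides) -> "ChainConfig":
        from dataclasses import asdict

        kw = asdict(self)
        kw.update(overrides)
        return ChainConfig(**kw)


@dataclass
class ChainSummary:
    """Thinned draws and accumulated co-grouping counts from one chain.

    ``co_gene_counts[i, i']`` is the number of kept sweeps in which genes i
    and i' shared a global cluster; ``co_sample_counts`` likewise for
    samples sharing a context.  With fixed contexts, ``co_local_counts[r]``
    counts sweeps in which two genes shared a *local* cluster within
    context r (``l[c_i, r] == l[c_i', r]``); in free-context runs (with
    ``track_local=True``) it is per sample column j, using each sample's
    current context.
    """

    co_gene_counts: np.ndarray
    co_sample_counts: np.ndarray
    co_local_counts: Optional[list[np.ndarray]]
    n_kept: int
    kept_draws: list[AllocationState] = field(default_factory=list)
    final_state: Optional[AllocationState] = None
    final_concentrations: Optional[Concentrations] = None
    seed: Optional[int] = None


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 0-based integers in first-occurrence order."""
    out = np.empty(len(labels), dtype=np.int64)
    seen: dict = {}
    for i, lab in enumerate(labels.tolist()):
        out[i] = seen.setdefault(lab, len(seen))
    return out


def initialize_state(X: ExpressionMatrix, config: ChainConfig) -> AllocationState:
    """Deterministic initial state: singleton gene clusters, one context
    (or the fixed contexts), identity local clustering."""
    n, m = X.values.shape
    C = np.arange(n, dtype=np.int64)
    if config.fixed_contexts is not None:
        if len(config.fixed_contexts) != m:
            raise ValueError("fixed_contexts length must equal the number of samples")
        D = config.fixed_contexts.copy()
    else:
        D = np.zeros(m, dtype=np.int64)
    R = int(D.max()) + 1
    L = np.tile(np.arange(n, dtype=np.int64)[:, None], (1, R))
    return AllocationState(C, D, L)


class _Sampler:
    """Mutable chain state with incremental sufficient statistics.

    Global-cluster statistics ``gn`` (gene count) and ``gs1``/``gs2``
    (per-sample sums of values and squares) live in capacity-backed arrays
    of N rows (clusters) and M columns (contexts for ``L``); ``Q`` and
    ``R`` give the occupied prefix.  Local-cluster aggregates are small
    indicator contractions of the global statistics, rebuilt on demand.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        state: AllocationState,
        prior: ConjugatePrior,
        conc: Concentrations,
        config: ChainConfig,
        rng: np.random.Generator,
    ):
        self.X = np.ascontiguousarray(X.values)
        self.Xsq = self.X * self.X
        self.N, self.M = self.X.shape
        self.C = state.C.copy()
        self.D = state.D.copy()
        self.Q = state.n_global
        self.R = state.n_contexts
        self._L = np.zeros((self.N, self.M), dtype=np.int64)
        self._L[: self.Q, : self.R] = state.L
        self.prior = prior
        self.conc = conc
        self.config = config
        self.rng = rng
        self.m0 = np.ascontiguousarray(prior.m0)
        if self.m0.shape != (self.M,):
            raise ValueError("prior m0 must have one entry per sample")
        self._gn = np.zeros(self.N, dtype=np.int64)
        self._gs1 = np.zeros((self.N, self.M))
        self._gs2 = np.zeros((self.N, self.M))
        self._rebuild_global_stats()
        # gammaln(a + k/2) table for the compiled kernel's Student-t terms
        self._lgt = gammaln(prior.a + 0.5 * np.arange(self.N + 2))

    # ---- views and bookkeeping ---------------------------------------

    @property
    def gn(self) -> np.ndarray:
        return self._gn[: self.Q]

    @property
    def gs1(self) -> np.ndarray:
        return self._gs1[: self.Q]

    @property
    def gs2(self) -> np.ndarray:
        return self._gs2[: self.Q]

    @property
    def L(self) -> np.ndarray:
        return self._L[: self.Q, : self.R]

    def _rebuild_global_stats(self) -> None:
        self._gn[:] = 0
        self._gs1[:] = 0.0
        self._gs2[:] = 0.0
        np.add.at(self._gn, self.C, 1)
        np.add.at(self._gs1, self.C, self.X)
        np.add.at(self._gs2, self.C, self.Xsq)

    def _compact_local_labels(self, r: int) -> None:
        lab = self._L[: self.Q, r]
        present = np.unique(lab)
        if len(present) == lab.max() + 1:
            return
        remap = np.full(lab.max() + 1, -1, dtype=np.int64)
        remap[present] = np.arange(len(present))
        self._L[: self.Q, r] = remap[lab]

    def _drop_global_cluster(self, q: int) -> None:
        Q = self.Q
        self._gn[q : Q - 1] = self._gn[q + 1 : Q]
        self._gs1[q : Q - 1] = self._gs1[q + 1 : Q]
        self._gs2[q : Q - 1] = self._gs2[q + 1 : Q]
        self._L[q : Q - 1, : self.R] = self._L[q + 1 : Q, : self.R]
        self.Q = Q - 1
        self.C[self.C > q] -= 1
        for r in range(self.R):
            self._compact_local_labels(r)

    def _drop_context(self, r: int) -> None:
        R = self.R
        self._L[: self.Q, r : R - 1] = self._L[: self.Q, r + 1 : R]
        self.R = R - 1
        self.D[self.D > r] -= 1

    def _add_context(self, col: np.ndarray) -> None:
        self._L[: self.Q, self.R] = _canonical_labels(col)
        self.R += 1

    def _gumbel_argmax(self, logits: np.ndarray) -> int:
        return int(np.argmax(logits + self.rng.gumbel(size=len(logits))))

    # ---- gene allocation sweep ---------------------------------------

    def update_gene_allocations(self) -> None:
        if self.config.engine == "numba":
            from .kernels import gene_sweep

            p = self.prior
            u = self.rng.random(self.N * (1 + self.R))
            self.Q = int(
                gene_sweep(
                    self.X, self.Xsq, self.C, self.D,
                    self._gn, self._gs1, self._gs2, self._L,
                    self.Q, self.R,
                    self.m0, p.lam, p.a, p.tau, self._lgt,
                    self.conc.alpha, self.conc.phi,
                    self.config.prior_only, u,
                )
            )
        else:
            self._update_gene_allocations_numpy()

    def _update_gene_allocations_numpy(self) -> None:
        """Reference gene sweep (vectorised numpy, Gumbel-max draws).

        For each gene the stacked candidate statistics — existing clusters'
        local-cluster stats per sample column, every (context, local
        cluster) seat for a hypothetical new cluster, and the R empty
        seats — are evaluated in a single Student-t predictive call; the
        new-cluster option marginalises the local seat per context and, if
        chosen, the seats are then drawn from their exact conditionals.
        """
        p = self.prior
        phi = self.conc.phi
        # context membership is constant during the gene sweep
        ctx_mask = self.D[None, :] == np.arange(self.R)[:, None]  # (R, M)
        col_idx = np.arange(self.M)[None, :]
        for i in range(self.N):
            xi = self.X[i]
            xi2 = self.Xsq[i]
            q0 = self.C[i]
            self._gn[q0] -= 1
            self._gs1[q0] -= xi
            self._gs2[q0] -= xi2
            self.C[i] = -1
            if self._gn[q0] == 0:
                self._drop_global_cluster(q0)
            Q, R, M = self.Q, self.R, self.M
            L = self.L
            log_prior = np.log(np.concatenate([self.gn, [self.conc.alpha]]))
            seat_data = None
            if self.config.prior_only:
                logits = log_prior
            else:
                # aggregate local-cluster stats for all contexts in one shot:
                # row offset_r + t holds the (context r, local cluster t) sums
                T_per_ctx = L.max(axis=0) + 1
                offsets = np.concatenate([[0], np.cumsum(T_per_ctx)[:-1]])
                Ttot = int(T_per_ctx.sum())
                glid = L + offsets[None, :]  # (Q, R) row ids
                W = np.zeros((Ttot, Q))
                W[glid.ravel(), np.repeat(np.arange(Q), R)] = 1.0
                tcount = W.sum(axis=1)
                ln = W @ self.gn
                LS1 = W @ self.gs1
                LS2 = W @ self.gs2
                # stack: Q existing-cluster rows, Ttot seat rows, R empty seats
                rows_A = glid[:, self.D]  # (Q, M)
                S_n = np.concatenate(
                    [ln[rows_A], np.broadcast_to(ln[:, None], (Ttot, M)), np.zeros((R, M))]
                )
                S_s1 = np.concatenate([LS1[rows_A, col_idx], LS1, np.zeros((R, M))])
                S_s2 = np.concatenate([LS2[rows_A, col_idx], LS2, np.zeros((R, M))])
                pred = nig_log_predictive_stats(
                    xi[None, :], S_n, S_s1, S_s2, self.m0[None, :], p.lam, p.a, p.tau
                )
                loglik = pred[:Q].sum(axis=1)
                ctx_of_seat = np.repeat(np.arange(R), T_per_ctx)
                seat_lik = (pred[Q : Q + Ttot] * ctx_mask[ctx_of_seat]).sum(axis=1)
                empty_lik = (pred[Q + Ttot :] * ctx_mask).sum(axis=1)
                log_tcount = np.log(tcount)
                log_phi = np.log(phi)
                log_new = -R * np.log(Q + phi)
                for r in range(R):
                    lo, hi = offsets[r], offsets[r] + T_per_ctx[r]
                    log_new += _logsumexp(
                        np.concatenate(
                            [log_tcount[lo:hi] + seat_lik[lo:hi],
                             [log_phi + empty_lik[r]]]
                        )
                    )
                seat_data = (offsets, T_per_ctx, log_tcount, seat_lik, empty_lik)
                logits = log_prior + np.concatenate([loglik, [log_new]])
            choice = self._gumbel_argmax(logits)
            if choice == Q:
                # open a new global cluster and seat it locally in every context
                self._gn[Q] = 1
                self._gs1[Q] = xi
                self._gs2[Q] = xi2
                for r in range(R):
                    if seat_data is None:
                        tc = np.bincount(self.L[:, r])
                        seat_logits = np.log(np.concatenate([tc, [phi]]))
                    else:
                        offsets, T_per_ctx, log_tcount, seat_lik, empty_lik = seat_data
                        lo, hi = offsets[r], offsets[r] + T_per_ctx[r]
                        seat_logits = np.concatenate(
                            [log_tcount[lo:hi] + seat_lik[lo:hi],
                             [np.log(phi) + empty_lik[r]]]
                        )
                    self._L[Q, r] = self._gumbel_argmax(seat_logits)
                self.Q = Q + 1
                self.C[i] = Q
            else:
                self._gn[choice] += 1
                self._gs1[choice] += xi
                self._gs2[choice] += xi2
                self.C[i] = choice

    # ---- local allocation sweep --------------------------------------

    def update_local_allocations(self) -> None:
        """Resample ``l[q, r]`` for every occupied (global cluster, context)
        pair; leaves C and D untouched."""
        p = self.prior
        phi = self.conc.phi
        for r in range(self.R):
            cols = np.flatnonzero(self.D == r)
            m0c = self.m0[cols]
            for q in range(self.Q):
                lab = self.L[:, r]
                t0 = lab[q]
                lab[q] = -1
                if not np.any(lab == t0):
                    lab[lab > t0] -= 1
                others = lab >= 0
                T = int(lab[others].max()) + 1 if others.any() else 0
                ind = lab == np.arange(T)[:, None]
                tcount = ind.sum(axis=1).astype(float)
                ln = (ind @ self.gn).astype(float)[:, None]
                ls1 = ind @ self.gs1[:, cols]
                ls2 = ind @ self.gs2[:, cols]
                # append the empty (new local cluster) candidate
                nn = np.vstack([ln, [[0.0]]])
                ss1 = np.vstack([ls1, np.zeros(len(cols))])
                ss2 = np.vstack([ls2, np.zeros(len(cols))])
                log_w = np.log(np.concatenate([tcount, [phi]]))
                if self.config.prior_only:
                    logits = log_w
                else:
                    bn = float(self.gn[q])
                    bs1 = self.gs1[q, cols]
                    bs2 = self.gs2[q, cols]
                    base = nig_log_marginal_stats(
                        nn, ss1, ss2, m0c[None, :], p.lam, p.a, p.tau
                    )
                    plus = nig_log_marginal_stats(
                        nn + bn, ss1 + bs1, ss2 + bs2,
                        m0c[None, :], p.lam, p.a, p.tau,
                    )
                    logits = log_w + (plus - base).sum(axis=1)
                lab[q] = self._gumbel_argmax(logits)

    # ---- context allocation sweep ------------------------------------

    def _crp_prior_partition(self, n_items: int) -> np.ndarray:
        """Sequential CRP(phi) draw of a partition of n_items items."""
        phi = self.conc.phi
        labels = np.empty(n_items, dtype=np.int64)
        counts: list[float] = []
        us = self.rng.random(n_items)
        for q in range(n_items):
            u = us[q] * (q + phi)
            acc = 0.0
            k = len(counts)
            for kk, c in enumerate(counts):
                acc += c
                if u < acc:
                    k = kk
                    break
            if k == len(counts):
                counts.append(1.0)
            else:
                counts[k] += 1.0
            labels[q] = k
        return labels

    def _context_loglik(self, j: int, lab: np.ndarray, cs1, cs2) -> float:
        """Log marginal of sample column j under local clustering ``lab``."""
        p = self.prior
        T = int(lab.max()) + 1
        tn = np.bincount(lab, weights=self.gn, minlength=T)
        ts1 = np.bincount(lab, weights=cs1, minlength=T)
        ts2 = np.bincount(lab, weights=cs2, minlength=T)
        return float(
            nig_log_marginal_stats(tn, ts1, ts2, self.m0[j], p.lam, p.a, p.tau).sum()
        )

    def update_context_allocations(self) -> None:
        if self.config.fixed_contexts is not None:
            return
        n_aux = self.config.n_aux_contexts
        beta = self.conc.beta
        for j in range(self.M):
            r0 = self.D[j]
            self.D[j] = -1
            saved_col = None
            if not np.any(self.D == r0):
                saved_col = self._L[: self.Q, r0].copy()
                self._drop_context(r0)
            R = self.R
            sizes = np.bincount(self.D[self.D >= 0], minlength=R).astype(float)
            aux_cols = [] if saved_col is None else [saved_col]
            while len(aux_cols) < n_aux:
                aux_cols.append(self._crp_prior_partition(self.Q))
            log_prior = np.concatenate(
                [np.log(sizes), np.full(n_aux, np.log(beta / n_aux))]
            )
            if self.config.prior_only:
                logits = log_prior
            else:
                xcol = self.X[:, j]
                cs1 = np.bincount(self.C, weights=xcol, minlength=self.Q)
                cs2 = np.bincount(self.C, weights=xcol * xcol, minlength=self.Q)
                logliks = [
                    self._context_loglik(j, self.L[:, r], cs1, cs2) for r in range(R)
                ] + [self._context_loglik(j, col, cs1, cs2) for col in aux_cols]
                logits = log_prior + np.array(logliks)
            choice = self._gumbel_argmax(logits)
            if choice < R:
                self.D[j] = choice
            else:
                self._add_context(aux_cols[choice - R])
                self.D[j] = self.R - 1

    # ---- concentration resampling ------------------------------------

    def resample_concentrations(self) -> None:
        """Auxiliary-variable update of (alpha, beta, phi) under Gamma(1,1)
        hyperpriors (Escobar-West for single partitions; the multi-restaurant
        extension for phi)."""
        if not self.config.resample_concentrations:
            return
        c = self.conc
        c.alpha = _resample_dp_concentration(c.alpha, self.N, self.Q, self.rng)
        c.beta = _resample_dp_concentration(c.beta, self.M, self.R, self.rng)
        n_tables = [int(self.L[:, r].max()) + 1 for r in range(self.R)]
        c.phi = _resample_shared_concentration(c.phi, self.Q, n_tables, self.rng)

    # ---- sweep + snapshot --------------------------------------------

    def sweep(self) -> None:
        self.update_gene_allocations()
        self.update_local_allocations()
        self.update_context_allocations()
        self.resample_concentrations()

    def snapshot(self) -> AllocationState:
        return AllocationState(self.C.copy(), self.D.copy(), self.L.copy())


def _resample_dp_concentration(
    conc: float, n_items: int, n_groups: int, rng: np.random.Generator,
    g1: float = 1.0, g2: float = 1.0,
) -> float:
    eta = rng.beta(conc + 1.0, n_items)
    odds = (g1 + n_groups - 1.0) / (n_items * (g2 - np.log(eta)))
    shape = g1 + n_groups if rng.random() < odds / (1.0 + odds) else g1 + n_groups - 1.0
    return float(rng.gamma(shape, 1.0 / (g2 - np.log(eta))))


def _resample_shared_concentration(
    conc: float, n_items: int, n_tables: Sequence[int], rng: np.random.Generator,
    g1: float = 1.0, g2: float = 1.0,
) -> float:
    etas = rng.beta(conc + 1.0, n_items, size=len(n_tables))
    s = rng.random(len(n_tables)) < n_items / (n_items + conc)
    shape = g1 + sum(n_tables) - int(s.sum())
    rate = g2 - float(np.log(etas).sum())
    return float(rng.gamma(shape, 1.0 / rate))


def run_chain(
    X: ExpressionMatrix,
    config: ChainConfig | None = None,
    prior: ConjugatePrior | None = None,
    conc: Concentrations | None = None,
) -> ChainSummary:
    """Run one collapsed Gibbs chain and accumulate co-grouping counts.

    Performs ``config.n_burnin`` discarded sweeps followed by
    ``config.n_keep * config.thin`` sweeps of which every ``thin``-th is
    retained.  Each retained sweep increments the gene/gene, sample/sample
    and (optionally) local co-grouping count matrices; dividing by
    ``n_kept`` (see :func:`dcim.summaries.ppp_from_counts`) yields
    posterior pairwise probabilities.
    """
    if X.n_genes < 2 or X.n_samples < 2:
        raise ValueError("model entry requires at least 2 genes and 2 samples")
    config = config or ChainConfig()
    prior = prior or ConjugatePrior.empirical(X)
    conc = conc or Concentrations()
    rng = np.random.default_rng(config.seed)
    state = initialize_state(X, config)
    # copy so a caller's Concentrations object is not mutated by resampling
    conc = Concentrations(conc.alpha, conc.beta, conc.phi)
    s = _Sampler(X, state, prior, conc, config, rng)

    N, M = X.values.shape
    co_gene = np.zeros((N, N), dtype=np.int64)
    co_sample = np.zeros((M, M), dtype=np.int64)
    track_local = (
        config.track_local
        if config.track_local is not None
        else config.fixed_contexts is not None
    )
    if config.fixed_contexts is not None:
        n_local = int(config.fixed_contexts.max()) + 1
    else:
        n_local = M
    co_local = (
        [np.zeros((N, N), dtype=np.int64) for _ in range(n_local)]
        if track_local
        else None
    )

    for _ in range(config.n_burnin):
        s.sweep()
    kept = 0
    draws: list[AllocationState] = []
    for it in range(config.n_keep * config.thin):
        s.sweep()
        if (it + 1) % config.thin != 0:
            continue
        kept += 1
        co_gene += s.C[:, None] == s.C[None, :]
        co_sample += s.D[:, None] == s.D[None, :]
        if track_local:
            if config.fixed_contexts is not None:
                for r in range(n_local):
                    lab = s.L[s.C, r]
                    co_local[r] += lab[:, None] == lab[None, :]
            else:
                for j in range(M):
                    lab = s.L[s.C, s.D[j]]
                    co_local[j] += lab[:, None] == lab[None, :]
        if config.keep_draws:
            draws.append(s.snapshot())

    return ChainSummary(
        co_gene_counts=co_gene,
        co_sample_counts=co_sample,
        co_local_counts=co_local,
        n_kept=kept,
        kept_draws=draws,
        final_state=s.snapshot(),
        final_concentrations=Concentrations(conc.alpha, conc.beta, conc.phi),
        seed=config.seed,
    )
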