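"""Core domain types, CRP prior weights, and conjugate Gaussian marginals.

The expression model is collapsed: each local gene cluster's Gaussian
pattern (per-sample mean and variance) is never instantiated.  Every
likelihood evaluation uses the closed-form marginal of i.i.d. Gaussian
observations under a Normal-Inverse-Gamma (NIG) prior, or the matching
Student-t posterior predictive.  Variances are independent across sample
dimensions (diagonal covariance), so all marginals factorise into
per-sample one-dimensional terms parameterised by sufficient statistics
``(n, sum x, sum x^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ExpressionMatrix",
    "AllocationState",
    "ConjugatePrior",
    "Concentrations",
    "crp_weights",
    "nig_log_marginal",
    "nig_log_marginal_stats",
    "nig_log_predictive",
    "nig_log_predictive_stats",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class ExpressionMatrix:
    """A genes-by-samples real expression matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_samples)``; finite, no missing values.
    gene_ids, sample_ids
        Unique string identifiers aligned with rows / columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("expression matrix must be non-empty")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match row count")
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != m:
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "expression matrix contains non-finite values; "
                "impute or filter before model entry"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class AllocationState:
    """The three allocation structures of the model.

    ``C[i] = q`` assigns gene ``i`` to global cluster ``q``; ``D[j] = r``
    assigns sample ``j`` to context ``r``; ``L[q, r] = t`` groups global
    cluster ``q`` into local cluster ``t`` within context ``r``.  Labels are
    0-based and contiguous at every level (compacted whenever a group
    empties).
    """

    C: np.ndarray
    D: np.ndarray
    L: np.ndarray  # shape (Q, R)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=np.int64)

    @property
    def n_global(self) -> int:
        """Number of occupied global gene clusters Q."""
        return self.L.shape[0]

    @property
    def n_contexts(self) -> int:
        """Number of occupied contexts R."""
        return self.L.shape[1]

    def validate(self) -> None:
        """Raise if labels are not contiguous or L is inconsistent."""
        Q, R = self.L.shape
        if sorted(set(self.C.tolist())) != list(range(Q)):
            raise ValueError("gene labels C are not contiguous 0..Q-1")
        if sorted(set(self.D.tolist())) != list(range(R)):
            raise ValueError("context labels D are not contiguous 0..R-1")
        for r in range(R):
            col = self.L[:, r]
            if sorted(set(col.tolist())) != list(range(col.max() + 1)):
                raise ValueError(f"local labels in context {r} are not contiguous")

    def copy(self) -> "AllocationState":
        return AllocationState(self.C.copy(), self.D.copy(), self.L.copy())


@dataclass
class ConjugatePrior:
    """Normal-Inverse-Gamma prior for one expression pattern dimension.

    Per sample dimension ``j`` the pattern mean and variance follow
    ``sigma^2 ~ InvGamma(a, tau)`` and ``mu | sigma^2 ~ N(m0_j, sigma^2 /
    lam)``.  ``m0`` is a length-M vector (one location per sample); the
    scale parameters are shared across dimensions.
    """

    m0: np.ndarray
    lam: float = 1.0
    a: float = 2.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.m0 = np.atleast_1d(np.asarray(self.m0, dtype=float))
        if not np.all(np.isfinite(self.m0)):
            raise ValueError("prior location m0 must be finite")
        for name in ("lam", "a", "tau"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"prior parameter {name} must be strictly positive")

    @classmethod
    def empirical(cls, X: ExpressionMatrix, lam: float = 1.0, a: float = 2.0) -> "ConjugatePrior":
        """Weakly informative, scale-matched default: ``m0`` = column means,
        ``tau`` = overall data variance."""
        return cls(
            m0=X.values.mean(axis=0),
            lam=lam,
            a=a,
            tau=float(max(X.values.var(), 1e-12)),
        )


@dataclass
class Concentrations:
    """Dirichlet-process concentration parameters.

    ``alpha`` governs the gene-level partition, ``beta`` the sample-to-context
    partition, and ``phi`` the grouping of global clusters into local
    clusters within each context.
    """

    alpha: float = 1.0
    beta: float = 1.0
    phi: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "phi"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"concentration {name} must be strictly positive")


def crp_weights(
    group_sizes: Sequence[int] | np.ndarray,
    concentration: float,
    excluded_total: int | None = None,
) -> np.ndarray:
    """Chinese-restaurant-process allocation probabilities.

    Returns the length ``K+1`` probability vector
    ``(n_1, ..., n_K, concentration) / (total + concentration)``: the
    probability of joining each of the K existing groups followed by the
    probability of opening a new group.

    Parameters
    ----------
    group_sizes
        Occupancy of the existing groups (non-negative integers).
    concentration
        DP concentration parameter, strictly positive.
    excluded_total
        Total number of items already allocated (the item being placed is
        excluded).  Defaults to ``sum(group_sizes)``; if given it must equal
        that sum.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    if sizes.ndim != 1:
        raise ValueError("group_sizes must be one-dimensional")
    if np.any(sizes < 0):
        raise ValueError("group sizes must be non-negative")
    if not concentration > 0:
        raise ValueError("concentration must be strictly positive")
    total = float(sizes.sum())
    if excluded_total is not None and not np.isclose(total, excluded_total):
        raise ValueError(
            f"group_sizes sum to {total}, expected excluded_total={excluded_total}"
        )
    w = np.concatenate([sizes, [concentration]])
    return w / (total + concentration)


def _nig_posterior_params(n, s1, s2, m0, lam, a, tau):
    """Posterior NIG parameters given sufficient statistics.

    Uses the completed-square form ``tau_n = tau + (s2 + lam m0^2 -
    lam_n m_n^2)/2`` which is well defined at ``n = 0``.
    """
    lam_n = lam + n
    m_n = (lam * m0 + s1) / lam_n
    a_n = a + 0.5 * n
    tau_n = tau + 0.5 * (s2 + lam * m0 * m0 - lam_n * m_n * m_n)
    return lam_n, m_n, a_n, tau_n


def nig_log_marginal_stats(n, s1, s2, m0, lam, a, tau):
    """Log marginal likelihood of Gaussian data summarised by ``(n, s1, s2)``.

    Vectorised over broadcastable statistic arrays; ``n = 0`` entries give 0.
    """
    n = np.asarray(n, dtype=float)
    lam_n, _, a_n, tau_n = _nig_posterior_params(n, s1, s2, m0, lam, a, tau)
    # clamp: tau_n can dip epsilon-negative on degenerate single-point data
    tau_n = np.maximum(tau_n, 1e-300)
    return (
        -n * _HALF_LOG_2PI
        + 0.5 * (np.log(lam) - np.log(lam_n))
        + gammaln(a_n)
        - gammaln(a)
        + a * np.log(tau)
        - a_n * np.log(tau_n)
    )


def nig_log_marginal(values, m0: float, lam: float, a: float, tau: float) -> float:
    """Log marginal likelihood of one-dimensional values under the NIG prior.

    ``log integral prod_v N(v | mu, s2) NIG(mu, s2 | m0, lam, a, tau) dmu ds2``;
    an empty value set returns 0 (empty product).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return 0.0
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return float(
        nig_log_marginal_stats(v.size, v.sum(), np.dot(v, v), m0, lam, a, tau)
    )


def nig_log_predictive_stats(x, n, s1, s2, m0, lam, a, tau):
    """Log posterior-predictive density of ``x`` given statistics ``(n, s1, s2)``.

    The predictive is Student-t with ``2 a_n`` degrees of freedom, location
    ``m_n`` and squared scale ``tau_n (lam_n + 1) / (a_n lam_n)``; with empty
    statistics it reduces to the prior predictive.  Vectorised over
    broadcastable arrays.
    """
    lam_n, m_n, a_n, tau_n = _nig_posterior_params(
        np.asarray(n, dtype=float), s1, s2, m0, lam, a, tau
    )
    tau_n = np.maximum(tau_n, 1e-300)
    df = 2.0 * a_n
    scale2 = tau_n * (lam_n + 1.0) / (a_n * lam_n)
    z2 = (x - m_n) ** 2 / scale2
    return (
        gammaln(0.5 * (df + 1.0))
        - gammaln(0.5 * df)
        - 0.5 * np.log(df * np.pi)
        - 0.5 * np.log(scale2)
        - 0.5 * (df + 1.0) * np.log1p(z2 / df)
    )


def nig_log_predictive(x: float, n, s1, s2, m0, lam, a, tau) -> float:
    """Scalar convenience wrapper around :func:`nig_log_predictive_stats`."""
    return float(nig_log_predictive_stats(x, n, s1, s2, m0, lam, a, tau))
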