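"""Compiled inner loop for the gene-allocation sweep.

The gene sweep dominates chain runtime (one Student-t predictive per gene,
candidate cluster and sample column).  This kernel performs a full scan in
one call, mutating the allocation vector and the capacity-backed
global-cluster sufficient statistics in place.  Categorical draws use
inverse-CDF sampling on a pre-drawn uniform buffer (one uniform for the
cluster choice plus one per context for the local seats of a newly opened
cluster), so a chain is reproducible from its seed alone.

The arithmetic mirrors :mod:`dcim.model`: ``lgt[k]`` must hold
``gammaln(a + k / 2)`` so the Student-t normalising constants come from two
table lookups per evaluation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["gene_sweep"]

_NEG_INF = -1.0e300


@njit(cache=True)
def gene_sweep(
    X, Xsq, C, D, gn, gs1, gs2, L, Q, R,
    m0, lam, a, tau, lgt, alpha, phi, prior_only, u,
):  # pragma: no cover - exercised via run_chain
    N, M = X.shape
    cap = N + 1
    ln = np.zeros((R, cap))
    tcount = np.zeros((R, cap))
    ls1 = np.zeros((R, cap, M))
    ls2 = np.zeros((R, cap, M))
    P = np.zeros((R, cap, M))
    SL = np.zeros((R, cap))
    SE = np.zeros(R)
    Tr = np.zeros(R, np.int64)
    p0 = np.zeros(M)
    logits = np.zeros(cap)
    remap = np.zeros(cap, np.int64)

    for i in range(N):
        xrow = X[i]
        x2row = Xsq[i]
        q0 = C[i]
        gn[q0] -= 1
        for j in range(M):
            gs1[q0, j] -= xrow[j]
            gs2[q0, j] -= x2row[j]
        C[i] = -1
        if gn[q0] == 0:
            for q in range(q0, Q - 1):
                gn[q] = gn[q + 1]
                for j in range(M):
                    gs1[q, j] = gs1[q + 1, j]
                    gs2[q, j] = gs2[q + 1, j]
                for r in range(R):
                    L[q, r] = L[q + 1, r]
            Q -= 1
            for g in range(N):
                if C[g] > q0:
                    C[g] -= 1
            # compact local labels that may have emptied
            for r in range(R):
                maxt = 0
                for q in range(Q):
                    if L[q, r] > maxt:
                        maxt = L[q, r]
                for t in range(maxt + 1):
                    tcount[r, t] = 0.0
                for q in range(Q):
                    tcount[r, L[q, r]] += 1.0
                shift = 0
                for t in range(maxt + 1):
                    remap[t] = t - shift
                    if tcount[r, t] == 0.0:
                        shift += 1
                if shift > 0:
                    for q in range(Q):
                        L[q, r] = remap[L[q, r]]

        # local-cluster occupancy (needed for seats in all modes)
        for r in range(R):
            maxt = 0
            for q in range(Q):
                if L[q, r] + 1 > maxt:
                    maxt = L[q, r] + 1
            Tr[r] = maxt
            for t in range(maxt):
                tcount[r, t] = 0.0
            for q in range(Q):
                tcount[r, L[q, r]] += 1.0

        log_new = 0.0
        if not prior_only:
            for r in range(R):
                for t in range(Tr[r]):
                    ln[r, t] = 0.0
                    for j in range(M):
                        ls1[r, t, j] = 0.0
                        ls2[r, t, j] = 0.0
            for q in range(Q):
                for r in range(R):
                    ln[r, L[q, r]] += gn[q]
                for j in range(M):
                    r = D[j]
                    t = L[q, r]
                    ls1[r, t, j] += gs1[q, j]
                    ls2[r, t, j] += gs2[q, j]
            # Student-t predictive of x_ij per (context, local cluster, j)
            for j in range(M):
                r = D[j]
                x = xrow[j]
                mj = m0[j]
                for t in range(Tr[r]):
                    n = ln[r, t]
                    lam_n = lam + n
                    m_n = (lam * mj + ls1[r, t, j]) / lam_n
                    tau_n = tau + 0.5 * (
                        ls2[r, t, j] + lam * mj * mj - lam_n * m_n * m_n
                    )
                    if tau_n < 1e-300:
                        tau_n = 1e-300
                    k = int(n)
                    df = 2.0 * a + n
                    a_n = a + 0.5 * n
                    scale2 = tau_n * (lam_n + 1.0) / (a_n * lam_n)
                    z2 = (x - m_n) * (x - m_n) / scale2
                    P[r, t, j] = (
                        lgt[k + 1]
                        - lgt[k]
                        - 0.5 * math.log(df * math.pi)
                        - 0.5 * math.log(scale2)
                        - 0.5 * (df + 1.0) * math.log1p(z2 / df)
                    )
                # prior predictive (empty seat), identical for every context
                df = 2.0 * a
                scale2 = tau * (lam + 1.0) / (a * lam)
                z2 = (x - mj) * (x - mj) / scale2
                p0[j] = (
                    lgt[1]
                    - lgt[0]
                    - 0.5 * math.log(df * math.pi)
                    - 0.5 * math.log(scale2)
                    - 0.5 * (df + 1.0) * math.log1p(z2 / df)
                )
            # new-cluster option: marginalise the seat in every context
            log_new = -R * math.log(Q + phi)
            log_phi = math.log(phi)
            for r in range(R):
                se = log_phi
                for j in range(M):
                    if D[j] == r:
                        se += p0[j]
                SE[r] = se
                best = se
                for t in range(Tr[r]):
                    s = math.log(tcount[r, t])
                    for j in range(M):
                        if D[j] == r:
                            s += P[r, t, j]
                    SL[r, t] = s
                    if s > best:
                        best = s
                acc = math.exp(se - best)
                for t in range(Tr[r]):
                    acc += math.exp(SL[r, t] - best)
                log_new += best + math.log(acc)

        # cluster logits and inverse-CDF draw
        for q in range(Q):
            logits[q] = math.log(gn[q])
            if not prior_only:
                acc = 0.0
                for j in range(M):
                    acc += P[D[j], L[q, D[j]], j]
                logits[q] += acc
        logits[Q] = math.log(alpha) + log_new
        best = _NEG_INF
        for q in range(Q + 1):
            if logits[q] > best:
                best = logits[q]
        z = 0.0
        for q in range(Q + 1):
            z += math.exp(logits[q] - best)
        target = u[i * (1 + R)] * z
        acc = 0.0
        choice = Q
        for q in range(Q + 1):
            acc += math.exp(logits[q] - best)
            if target < acc:
                choice = q
                break
        if choice == Q:
            gn[Q] = 1
            for j in range(M):
                gs1[Q, j] = xrow[j]
                gs2[Q, j] = x2row[j]
            for r in range(R):
                T = Tr[r]
                if prior_only:
                    best = math.log(phi)
                    for t in range(T):
                        s = math.log(tcount[r, t])
                        SL[r, t] = s
                        if s > best:
                            best = s
                    se = math.log(phi)
                else:
                    se = SE[r]
                    best = se
                    for t in range(T):
                        if SL[r, t] > best:
                            best = SL[r, t]
                z = math.exp(se - best)
                for t in range(T):
                    z += math.exp(SL[r, t] - best)
                target = u[i * (1 + R) + 1 + r] * z
                acc = 0.0
                seat = T
                for t in range(T):
                    acc += math.exp(SL[r, t] - best)
                    if target < acc:
                        seat = t
                        break
                L[Q, r] = seat
            Q += 1
            C[i] = Q - 1
        else:
            gn[choice] += 1
            for j in range(M):
                gs1[choice, j] += xrow[j]
                gs2[choice, j] += x2row[j]
            C[i] = choice
    return Q
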