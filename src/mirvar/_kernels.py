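"""Numba kernels for the folding dynamic programs.

All kernels work on 0-based integer-encoded sequences (A=0, C=1, G=2, U=3)
and a precomputed pair-type matrix ``ptype`` (6 allowed pair classes, -1 for
a disallowed pair).  Loop-energy tables are passed pre-extrapolated to the
sequence length.  The partition-function kernels use per-nucleotide scaling
(every nucleotide consumed by a subproblem carries one factor ``s``) so that
Boltzmann sums for long sequences stay inside double range; probabilities
are scale-free ratios.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1.0e30


@njit(cache=True)
def fill_nussinov(ptype, min_loop):
    n = ptype.shape[0]
    N = np.zeros((n, n), dtype=np.int64)
    for d in range(min_loop + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = N[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if ptype[i, k] >= 0:
                    inner = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


@njit(cache=True)
def fill_mfe(ptype, hairpinE, bulgeE, internalE, stackE, ml_a, ml_b, ml_c,
             min_loop, max_int):
    n = ptype.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M1 = np.full((n, n), INF)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptype[i, j]
            if pt >= 0 and d > min_loop:
                best = hairpinE[d - 1]
                for k in range(i + 1, j):
                    l1 = k - i - 1
                    if l1 > max_int:
                        break
                    for l in range(j - 1, k, -1):
                        l2 = j - l - 1
                        if l2 > max_int:
                            break
                        if ptype[k, l] < 0 or l - k <= min_loop:
                            continue
                        vin = V[k, l]
                        if vin >= INF / 2:
                            continue
                        size = l1 + l2
                        if size == 0:
                            e = stackE[pt, ptype[k, l]]
                        elif l1 == 0 or l2 == 0:
                            e = bulgeE[size]
                        else:
                            e = internalE[size]
                        if e + vin < best:
                            best = e + vin
                for k in range(i + 2, j - 1):
                    m_ = M[i + 1, k - 1]
                    m1_ = M1[k, j - 1]
                    if m_ < INF / 2 and m1_ < INF / 2:
                        cand = ml_a + ml_b + m_ + m1_
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M1: exactly one branch starting at i, trailing unpaired
            x = INF
            if M1[i, j - 1] < INF / 2:
                x = M1[i, j - 1] + ml_c
            if V[i, j] < INF / 2 and V[i, j] + ml_b < x:
                x = V[i, j] + ml_b
            M1[i, j] = x
            # M: >= 1 branch anywhere
            x = INF
            if M[i + 1, j] < INF / 2:
                x = M[i + 1, j] + ml_c
            if M[i, j - 1] < INF / 2 and M[i, j - 1] + ml_c < x:
                x = M[i, j - 1] + ml_c
            if V[i, j] < INF / 2 and V[i, j] + ml_b < x:
                x = V[i, j] + ml_b
            for k in range(i + 1, j + 1):
                if M[i, k - 1] < INF / 2 and V[k, j] < INF / 2:
                    cand = M[i, k - 1] + V[k, j] + ml_b
                    if cand < x:
                        x = cand
            M[i, j] = x
    W = np.zeros(n + 1)
    for j in range(n):
        W[j + 1] = W[j]
        for i in range(0, j + 1):
            if V[i, j] < INF / 2 and W[i] + V[i, j] < W[j + 1]:
                W[j + 1] = W[i] + V[i, j]
    return V, M, M1, W


@njit(cache=True)
def fill_inside(ptype, bf_hairpin, bf_bulge, bf_internal, bf_stack,
                bf_ab, bf_b, cs, s, spow, min_loop, max_int):
    """McCaskill inside pass.  Returns (qb, qm, qm1, qe, qs_suf).

    qb[i,j]: PF of i..j given (i,j) paired.  qm: multiloop segment with >= 1
    branch.  qm1: exactly one branch starting at i plus trailing unpaired.
    qe[k]: PF of the first k bases (external); qs_suf[i]: PF of suffix i..n-1.
    All scaled by s per nucleotide.
    """
    n = ptype.shape[0]
    qb = np.zeros((n, n))
    qm = np.zeros((n, n))
    qm1 = np.zeros((n, n))
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptype[i, j]
            if pt >= 0 and d > min_loop:
                x = spow[d + 1] * bf_hairpin[d - 1]
                for k in range(i + 1, j):
                    l1 = k - i - 1
                    if l1 > max_int:
                        break
                    for l in range(j - 1, k, -1):
                        l2 = j - l - 1
                        if l2 > max_int:
                            break
                        if ptype[k, l] < 0 or l - k <= min_loop:
                            continue
                        q_in = qb[k, l]
                        if q_in <= 0.0:
                            continue
                        size = l1 + l2
                        if size == 0:
                            w = bf_stack[pt, ptype[k, l]]
                        elif l1 == 0 or l2 == 0:
                            w = bf_bulge[size]
                        else:
                            w = bf_internal[size]
                        x += w * spow[size + 2] * q_in
                acc = 0.0
                for k in range(i + 2, j - 1):
                    acc += qm[i + 1, k - 1] * qm1[k, j - 1]
                x += bf_ab * s * s * acc
                qb[i, j] = x
            # qm1
            qm1[i, j] = qm1[i, j - 1] * cs + qb[i, j] * bf_b
            # qm: decompose by start k of the last branch
            acc = 0.0
            csp = 1.0
            for k in range(i, j + 1):
                left = csp
                if k > i:
                    left += qm[i, k - 1]
                acc += left * qm1[k, j]
                csp *= cs
            qm[i, j] = acc
    qe = np.zeros(n + 1)
    qe[0] = 1.0
    for jj in range(1, n + 1):
        x = qe[jj - 1] * s
        for i in range(0, jj):
            if qb[i, jj - 1] > 0.0:
                x += qe[i] * qb[i, jj - 1]
        qe[jj] = x
    qs_suf = np.zeros(n + 1)
    qs_suf[n] = 1.0
    for i in range(n - 1, -1, -1):
        x = qs_suf[i + 1] * s
        for j in range(i + min_loop + 1, n):
            if qb[i, j] > 0.0:
                x += qb[i, j] * qs_suf[j + 1]
        qs_suf[i] = x
    return qb, qm, qm1, qe, qs_suf


@njit(cache=True)
def fill_outside(ptype, qb, qm, qm1, qe, qs_suf,
                 bf_bulge, bf_internal, bf_stack,
                 bf_ab, bf_b, cs, s, spow, min_loop, max_int):
    """Outside pass (adjoint of the inside recursions); returns the base-pair
    probability matrix."""
    n = ptype.shape[0]
    Z = qe[n]
    ob = np.zeros((n, n))
    om = np.zeros((n, n))
    om1 = np.zeros((n, n))
    p = np.zeros((n, n))
    for d in range(n - 1, min_loop, -1):
        for i in range(0, n - d):
            j = i + d
            o = om[i, j]
            if o > 0.0:
                csp = 1.0
                for k in range(i, j + 1):
                    left = csp
                    if k > i:
                        left += qm[i, k - 1]
                        om[i, k - 1] += o * qm1[k, j]
                    om1[k, j] += o * left
                    csp *= cs
            o1 = om1[i, j]
            if o1 > 0.0:
                csp = 1.0
                for l in range(j, i, -1):
                    if qb[i, l] > 0.0:
                        ob[i, l] += o1 * bf_b * csp
                    csp *= cs
            if ptype[i, j] >= 0 and qb[i, j] > 0.0:
                obij = ob[i, j] + qe[i] * qs_suf[j + 1]
                ob[i, j] = obij
                if obij > 0.0:
                    p[i, j] = qb[i, j] * obij / Z
                    pt = ptype[i, j]
                    for k in range(i + 1, j):
                        l1 = k - i - 1
                        if l1 > max_int:
                            break
                        for l in range(j - 1, k, -1):
                            l2 = j - l - 1
                            if l2 > max_int:
                                break
                            if ptype[k, l] < 0 or l - k <= min_loop:
                                continue
                            if qb[k, l] <= 0.0:
                                continue
                            size = l1 + l2
                            if size == 0:
                                w = bf_stack[pt, ptype[k, l]]
                            elif l1 == 0 or l2 == 0:
                                w = bf_bulge[size]
                            else:
                                w = bf_internal[size]
                            ob[k, l] += obij * w * spow[size + 2]
                    f = obij * bf_ab * s * s
                    for k in range(i + 2, j - 1):
                        om[i + 1, k - 1] += f * qm1[k, j - 1]
                        om1[k, j - 1] += f * qm[i + 1, k - 1]
    for i in range(n):
        for j in range(i):
            p[i, j] = p[j, i]
    return p


@njit(cache=True)
def fill_mea(pmat, qvec, allowed, gamma):
    """Expected-accuracy DP: maximize sum(2*gamma*p_ij) + sum(q_unpaired)."""
    n = qvec.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        M[i, i] = qvec[i]
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            best = M[i, j - 1] + qvec[j]
            for k in range(i, j):
                if allowed[k, j] == 0 or pmat[k, j] <= 0.0:
                    continue
                cand = 2.0 * gamma * pmat[k, j]
                if k > i:
                    cand += M[i, k - 1]
                if k + 1 <= j - 1:
                    cand += M[k + 1, j - 1]
                if cand > best:
                    best = cand
            M[i, j] = best
    return M
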