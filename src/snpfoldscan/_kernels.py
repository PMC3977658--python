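"""Dynamic-programming kernels for the partition function and MFE folds.

All kernels are nopython-jitted plain loops over numpy arrays; they run
unchanged (only slower) with ``NUMBA_DISABLE_JIT=1``.  Indices are 0-based
here; the public API converts.

Notation follows the classic inside/outside scheme for pseudoknot-free
ensembles: ``qb[i, j]`` is the Boltzmann sum over structures on [i, j]
in which (i, j) pair; ``qm1``/``qm`` are the multiloop helpers (exactly
one branch starting at i / at least one branch); ``qf``/``qr`` are
exterior prefix/suffix sums.  Pair probabilities are propagated outside-in
over decreasing span, pushing each pair's probability mass down to the
pairs it can directly enclose (as a stack/interior loop or as a multiloop
branch).  An outer pair whose probability is below ``PRUNE`` is not
pushed; every pushed term is bounded by the outer probability itself, so
the truncation error per cell stays below ``n**2 * PRUNE``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: outer-pair probabilities below this are not propagated further inside
PRUNE = 1e-15


@njit(cache=False)
def inside(s, pt, stack, hairpin, internal, kT, h, maxloop, a, b, c):
    """Inside recursions; returns (qb, qm, qm1, qf, qr)."""
    n = s.shape[0]
    qb = np.zeros((n, n))
    qm = np.zeros((n, n))
    qm1 = np.zeros((n, n))

    for d in range(h + 1, n):
        for i in range(0, n - d):
            j = i + d
            ptype = pt[s[i], s[j]]
            if ptype != 0:
                # hairpin closed by (i, j)
                val = np.exp(-hairpin[d - 1] / kT)
                # stack / bulge / internal loop with inner pair (k, l)
                kmax = min(i + maxloop + 1, j - h - 2)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + h + 1, j - 1 - (maxloop - l1))
                    for l in range(lmin, j):
                        if qb[k, l] > 0.0:
                            l2 = j - l - 1
                            if l1 == 0 and l2 == 0:
                                e = stack[ptype, pt[s[k], s[l]]]
                            else:
                                e = internal[l1, l2]
                            if np.isfinite(e):
                                val += np.exp(-e / kT) * qb[k, l]
                # multiloop closed by (i, j): >= 2 inner branches
                ml = 0.0
                for u in range(i + 2, j):
                    if qm1[u, j - 1] > 0.0 and qm[i + 1, u - 1] > 0.0:
                        ml += qm[i + 1, u - 1] * qm1[u, j - 1]
                val += np.exp(-(a + b) / kT) * ml
                qb[i, j] = val

            # qm1: exactly one branch, starting at i, trailing unpaired
            v1 = 0.0
            for l in range(i + h + 1, j + 1):
                if qb[i, l] > 0.0:
                    v1 += qb[i, l] * np.exp(-(b + c * (j - l)) / kT)
            qm1[i, j] = v1

            # qm: at least one branch on [i, j]
            vm = 0.0
            for u in range(i, j + 1):
                if qm1[u, j] > 0.0:
                    left = np.exp(-c * (u - i) / kT)
                    if u > i:
                        left += qm[i, u - 1]
                    vm += left * qm1[u, j]
            qm[i, j] = vm

    # exterior prefix: qf[j] = partition over bases [0, j)
    qf = np.ones(n + 1)
    for j in range(1, n + 1):
        v = qf[j - 1]
        for k in range(0, j - 1 - h):
            if qb[k, j - 1] > 0.0:
                v += qf[k] * qb[k, j - 1]
        qf[j] = v

    # exterior suffix: qr[i] = partition over bases [i, n)
    qr = np.ones(n + 1)
    for i in range(n - 1, -1, -1):
        v = qr[i + 1]
        for l in range(i + h + 1, n):
            if qb[i, l] > 0.0:
                v += qb[i, l] * qr[l + 1]
        qr[i] = v

    return qb, qm, qm1, qf, qr


@njit(cache=False)
def outside(s, pt, stack, internal, kT, h, maxloop, a, b, c, qb, qm, qf, qr):
    """Pair probabilities from the inside arrays (outside recursion)."""
    n = s.shape[0]
    prob = np.zeros((n, n))
    # accumulated enclosed-pair coefficients: prob[i,j] = qb[i,j] * (ext + out[i,j])
    out = np.zeros((n, n))
    Q = qf[n]
    eml2 = np.exp(-(a + 2.0 * b) / kT)

    for d in range(n - 1, h, -1):
        for i in range(0, n - d):
            j = i + d
            if qb[i, j] <= 0.0:
                continue
            p = qb[i, j] * (qf[i] * qr[j + 1] / Q + out[i, j])
            prob[i, j] = p
            if p <= PRUNE:
                continue
            w = p / qb[i, j]
            # push to inner pairs of a stack / bulge / internal loop
            kmax = min(i + maxloop + 1, j - h - 2)
            for k in range(i + 1, kmax + 1):
                l1 = k - i - 1
                lmin = max(k + h + 1, j - 1 - (maxloop - l1))
                for l in range(lmin, j):
                    if qb[k, l] > 0.0:
                        l2 = j - l - 1
                        if l1 == 0 and l2 == 0:
                            e = stack[pt[s[i], s[j]], pt[s[k], s[l]]]
                        else:
                            e = internal[l1, l2]
                        if np.isfinite(e):
                            out[k, l] += w * np.exp(-e / kT)
            # push to multiloop branches (k, l) strictly inside (i, j):
            # coefficient = e^{-(a+2b)/kT} * [qmL*e(-c*rgap) + qmL*qmR + e(-c*lgap)*qmR]
            if j - i >= 2 * (h + 2) + 1:
                for k in range(i + 1, j - h - 1):
                    qmL = 0.0
                    if k - 1 >= i + 1:
                        qmL = qm[i + 1, k - 1]
                    eL = np.exp(-c * (k - i - 1) / kT)
                    for l in range(k + h + 1, j):
                        if qb[k, l] > 0.0:
                            qmR = 0.0
                            if j - 1 >= l + 1:
                                qmR = qm[l + 1, j - 1]
                            bracket = 0.0
                            if qmL > 0.0:
                                bracket += qmL * (np.exp(-c * (j - 1 - l) / kT) + qmR)
                            if qmR > 0.0:
                                bracket += eL * qmR
                            if bracket > 0.0:
                                out[k, l] += w * eml2 * bracket
    return prob


@njit(cache=False)
def mfe_tables(s, pt, stack, hairpin, internal, kT, h, maxloop, a, b, c):
    """Minimum-free-energy tables (vb, vm, vm1, f) mirroring the inside sums."""
    n = s.shape[0]
    INF = np.inf
    vb = np.full((n, n), INF)
    vm = np.full((n, n), INF)
    vm1 = np.full((n, n), INF)

    for d in range(h + 1, n):
        for i in range(0, n - d):
            j = i + d
            ptype = pt[s[i], s[j]]
            if ptype != 0:
                best = hairpin[d - 1]
                kmax = min(i + maxloop + 1, j - h - 2)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + h + 1, j - 1 - (maxloop - l1))
                    for l in range(lmin, j):
                        if np.isfinite(vb[k, l]):
                            l2 = j - l - 1
                            if l1 == 0 and l2 == 0:
                                e = stack[ptype, pt[s[k], s[l]]]
                            else:
                                e = internal[l1, l2]
                            if e + vb[k, l] < best:
                                best = e + vb[k, l]
                for u in range(i + 2, j):
                    if np.isfinite(vm[i + 1, u - 1]) and np.isfinite(vm1[u, j - 1]):
                        e = a + b + vm[i + 1, u - 1] + vm1[u, j - 1]
                        if e < best:
                            best = e
                vb[i, j] = best

            b1 = INF
            for l in range(i + h + 1, j + 1):
                if np.isfinite(vb[i, l]):
                    e = vb[i, l] + b + c * (j - l)
                    if e < b1:
                        b1 = e
            vm1[i, j] = b1

            bm = INF
            for u in range(i, j + 1):
                if np.isfinite(vm1[u, j]):
                    left = c * (u - i)
                    if u > i and vm[i, u - 1] < left:
                        left = vm[i, u - 1]
                    if left + vm1[u, j] < bm:
                        bm = left + vm1[u, j]
            vm[i, j] = bm

    f = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = f[j - 1]
        for k in range(0, j - 1 - h):
            if np.isfinite(vb[k, j - 1]) and f[k] + vb[k, j - 1] < best:
                best = f[k] + vb[k, j - 1]
        f[j] = best

    return vb, vm, vm1, f
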