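"""Numba-compiled hot loops.

Two loops dominate runtime and resist vectorisation: the Meuwissen-Luo
inbreeding recursion (sequential over animals) and the single-site Gibbs
sweep over animal effects (each animal's full conditional depends on the
freshly updated values of its relatives).  Both are kept free of any
random-number generation: the animal sweep consumes pre-drawn standard
normals so that all randomness flows through one numpy Generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def meuwissen_luo_inbreeding(sire, dam):
    """Inbreeding coefficients for a renumbered pedigree.

    ``sire``/``dam`` are int64 arrays of length n+1 (index 0 is the dummy
    unknown parent, codes are 1-based and parents precede offspring).
    Returns F of length n (0-based by animal code - 1).

    Uses the L-row construction: a_ii = sum_j L_ij^2 d_j where
    d_j = 0.5 - 0.25 (F_sj + F_dj) with F of an unknown parent taken as -1
    (so founders get d = 1).
    """
    n = sire.shape[0] - 1
    F = np.zeros(n + 1)
    F[0] = -1.0
    D = np.zeros(n + 1)
    v = np.zeros(n + 1)
    for i in range(1, n + 1):
        s = sire[i]
        d = dam[i]
        D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s == 0 or d == 0:
            F[i] = 0.0
            continue
        for j in range(i + 1):
            v[j] = 0.0
        v[i] = 1.0
        aii = 0.0
        for j in range(i, 0, -1):
            vj = v[j]
            if vj != 0.0:
                if sire[j] > 0:
                    v[sire[j]] += 0.5 * vj
                if dam[j] > 0:
                    v[dam[j]] += 0.5 * vj
                aii += vj * vj * D[j]
        F[i] = aii - 1.0
    return F[1:]


@njit(cache=True)
def animal_sweep(e, a, Rinv, Ginv, ai_ptr, ai_idx, ai_val, rp, ri, z):
    """One single-site Gibbs sweep over all animal-effect vectors.

    For animal k with record count c_k the full conditional of its T-vector
    a_k is N(P^-1 r, P^-1) with

        P = c_k R^-1 + A^kk G^-1
        r = R^-1 sum_i (e_i + a_k) - G^-1 sum_{j!=k} A^kj a_j

    where e_i are the current complete-data residuals of the animal's
    records (which include -a_k) and A^kj are entries of the sparse A
    inverse (CSR: ai_ptr/ai_idx/ai_val).  rp/ri map animals to record rows.
    z holds pre-drawn N(0,1) variates, one T-vector per animal.  e and a
    are updated in place.
    """
    n = a.shape[0]
    T = a.shape[1]
    P = np.empty((T, T))
    L = np.empty((T, T))
    s = np.empty(T)
    rsum = np.empty(T)
    r = np.empty(T)
    y = np.empty(T)
    mu = np.empty(T)
    for k in range(n):
        akk = 0.0
        for t in range(T):
            s[t] = 0.0
        for jj in range(ai_ptr[k], ai_ptr[k + 1]):
            j = ai_idx[jj]
            val = ai_val[jj]
            if j == k:
                akk = val
            else:
                for t in range(T):
                    s[t] += val * a[j, t]
        cnt = rp[k + 1] - rp[k]
        for t in range(T):
            rsum[t] = cnt * a[k, t]
        for ii in range(rp[k], rp[k + 1]):
            i = ri[ii]
            for t in range(T):
                rsum[t] += e[i, t]
        for t1 in range(T):
            acc = 0.0
            for t2 in range(T):
                acc += Rinv[t1, t2] * rsum[t2] - Ginv[t1, t2] * s[t2]
            r[t1] = acc
            for t2 in range(T):
                P[t1, t2] = cnt * Rinv[t1, t2] + akk * Ginv[t1, t2]
        # Cholesky P = L L'
        for t1 in range(T):
            for t2 in range(t1 + 1):
                acc = P[t1, t2]
                for t3 in range(t2):
                    acc -= L[t1, t3] * L[t2, t3]
                if t1 == t2:
                    if acc <= 0.0:
                        raise ValueError("non-PD animal-effect precision")
                    L[t1, t1] = np.sqrt(acc)
                else:
                    L[t1, t2] = acc / L[t2, t2]
        # mean = P^-1 r via forward/back substitution
        for t1 in range(T):
            acc = r[t1]
            for t2 in range(t1):
                acc -= L[t1, t2] * y[t2]
            y[t1] = acc / L[t1, t1]
        for t1 in range(T - 1, -1, -1):
            acc = y[t1]
            for t2 in range(t1 + 1, T):
                acc -= L[t2, t1] * mu[t2]
            mu[t1] = acc / L[t1, t1]
        # draw: a_new = mean + L'^-1 z_k
        for t1 in range(T - 1, -1, -1):
            acc = z[k, t1]
            for t2 in range(t1 + 1, T):
                acc -= L[t2, t1] * y[t2]
            y[t1] = acc / L[t1, t1]
        for t in range(T):
            newv = mu[t] + y[t]
            delta = newv - a[k, t]
            a[k, t] = newv
            for ii in range(rp[k], rp[k + 1]):
                e[ri[ii], t] -= delta
    return None
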