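"""Numba kernels: matrix exponentials, pruning likelihood and the MH chain.

Tree arrays follow the package's postorder layout (child id < parent id,
root last), so ``range(n_nodes)`` is a valid postorder and ``parent[u]``
indexes the branch above ``u``.
"""

import numpy as np
from numba import njit

NEG_INF = -1.0e308  # finite sentinel for impossible data inside kernels


@njit(cache=True)
def expm_small(A):
    """exp(A) for small dense A via scaling-and-squaring Taylor (order 16)."""
    k = A.shape[0]
    nrm = 0.0
    for i in range(k):
        s = 0.0
        for j in range(k):
            s += abs(A[i, j])
        if s > nrm:
            nrm = s
    s2 = 0
    while nrm > 0.5:
        nrm *= 0.5
        s2 += 1
    B = A / (2.0**s2)
    P = np.eye(k)
    T = np.eye(k)
    for m in range(1, 17):
        T = np.dot(T, B) / m
        P = P + T
    for _ in range(s2):
        P = np.dot(P, P)
    return P


@njit(cache=True)
def _inv_complex(V):
    """Gauss–Jordan inverse with partial pivoting; returns (Vinv, ok)."""
    k = V.shape[0]
    A = V.copy()
    B = np.eye(k).astype(np.complex128)
    for col in range(k):
        piv = col
        best = abs(A[col, col])
        for r in range(col + 1, k):
            if abs(A[r, col]) > best:
                best = abs(A[r, col])
                piv = r
        if best < 1e-13:
            return B, False
        if piv != col:
            for j in range(k):
                A[col, j], A[piv, j] = A[piv, j], A[col, j]
                B[col, j], B[piv, j] = B[piv, j], B[col, j]
        d = A[col, col]
        for j in range(k):
            A[col, j] /= d
            B[col, j] /= d
        for r in range(k):
            if r != col:
                f = A[r, col]
                if f != 0:
                    for j in range(k):
                        A[r, j] -= f * A[col, j]
                        B[r, j] -= f * B[col, j]
    return B, True


@njit(cache=True)
def edge_probs(Q, lengths):
    """P[u] = exp(Q * lengths[u]) for every node; eigendecomposition with
    Taylor fallback for defective or ill-conditioned Q."""
    n = lengths.shape[0]
    k = Q.shape[0]
    P = np.empty((n, k, k))
    Qc = Q.astype(np.complex128)
    lam, V = np.linalg.eig(Qc)
    Vinv, use_eig = _inv_complex(V)
    if use_eig:
        R = np.dot(np.dot(V, np.diag(lam)), Vinv)
        err = 0.0
        scale = 1.0
        for i in range(k):
            for j in range(k):
                d = abs(R[i, j].real - Q[i, j]) + abs(R[i, j].imag)
                if d > err:
                    err = d
                if abs(Q[i, j]) > scale:
                    scale = abs(Q[i, j])
        if not np.isfinite(err) or err > 1e-9 * scale:
            use_eig = False
    for u in range(n):
        t = lengths[u]
        if use_eig:
            E = np.dot(V * np.exp(lam * t), Vinv)
            for i in range(k):
                for j in range(k):
                    v = E[i, j].real
                    P[u, i, j] = v if v > 0.0 else 0.0
        else:
            E2 = expm_small(Q * t)
            for i in range(k):
                for j in range(k):
                    v = E2[i, j]
                    P[u, i, j] = v if v > 0.0 else 0.0
    return P


@njit(cache=True)
def prune_loglike(P, parent, child_flat, child_start, tip_partial, root_weights):
    """Felsenstein pruning over postordered arrays; returns log-likelihood."""
    n = parent.shape[0]
    k = P.shape[1]
    partial = np.zeros((n, k))
    logscale = 0.0
    for u in range(n):
        c0 = child_start[u]
        c1 = child_start[u + 1]
        if c1 == c0:  # tip
            for i in range(k):
                partial[u, i] = tip_partial[u, i]
            continue
        part = np.ones(k)
        for ci in range(c0, c1):
            c = child_flat[ci]
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += P[c, i, j] * partial[c, j]
                part[i] *= acc
        m = 0.0
        for i in range(k):
            if part[i] > m:
                m = part[i]
        if m <= 0.0:
            return NEG_INF
        for i in range(k):
            partial[u, i] = part[i] / m
        logscale += np.log(m)
    root = n - 1
    L = 0.0
    for i in range(k):
        L += root_weights[i] * partial[root, i]
    if L <= 0.0:
        return NEG_INF
    return np.log(L) + logscale


@njit(cache=True)
def mk_loglike(Q, lengths, parent, child_flat, child_start, tip_partial, root_weights):
    P = edge_probs(Q, lengths)
    return prune_loglike(P, parent, child_flat, child_start, tip_partial, root_weights)


@njit(cache=True)
def build_q(rates, assign, k):
    Q = np.zeros((k, k))
    for i in range(k):
        rs = 0.0
        for j in range(k):
            if i != j and assign[i, j] >= 0:
                Q[i, j] = rates[assign[i, j]]
                rs += Q[i, j]
        Q[i, i] = -rs
    return Q


@njit(cache=True)
def _log_prior_rates(rates, m):
    lp = 0.0
    for g in range(rates.shape[0]):
        lp += -np.log(m) - rates[g] / m
    return lp


@njit(cache=True)
def run_power_chain(
    seed,
    n_iter,
    thin,
    beta,
    rates0,
    m0,
    hyper_upper,
    update_mean,
    assign,
    k,
    lengths,
    parent,
    child_flat,
    child_start,
    tip_partial,
    root_weights,
    prop_scale,
    m_scale,
):
    """Metropolis–Hastings chain targeting prior × likelihood^beta.

    Rates get multiplicative log-normal proposals; the exponential-prior mean
    gets a reflected random walk on (0, hyper_upper].  Returns the
    log-likelihood trace (every iteration), thinned parameter samples, the
    acceptance counts and the final state.
    """
    np.random.seed(seed)
    n_free = rates0.shape[0]
    rates = rates0.copy()
    m = m0
    Q = build_q(rates, assign, k)
    ll = mk_loglike(Q, lengths, parent, child_flat, child_start, tip_partial, root_weights)
    lp = _log_prior_rates(rates, m)
    ll_trace = np.empty(n_iter)
    n_rec = n_iter // thin
    samples = np.empty((n_rec, n_free + 1))
    acc_rate = 0
    prop_rate = 0
    acc_m = 0
    prop_m = 0
    n_blocks = n_free + (1 if update_mean else 0)
    rec = 0
    for it in range(n_iter):
        which = np.random.randint(0, n_blocks)
        if which < n_free:
            prop_rate += 1
            g = which
            old = rates[g]
            new = old * np.exp(prop_scale * np.random.normal())
            rates[g] = new
            Qn = build_q(rates, assign, k)
            lln = mk_loglike(
                Qn, lengths, parent, child_flat, child_start, tip_partial, root_weights
            )
            lpn = _log_prior_rates(rates, m)
            # Jacobian log(new/old) for the log-scale move
            logr = beta * (lln - ll) + (lpn - lp) + np.log(new / old)
            if lln > NEG_INF / 2 and np.log(np.random.random()) < logr:
                ll = lln
                lp = lpn
                acc_rate += 1
            else:
                rates[g] = old
        else:
            prop_m += 1
            new_m = m + m_scale * np.random.normal()
            # reflect into (0, hyper_upper]
            if new_m < 0.0:
                new_m = -new_m
            if new_m > hyper_upper:
                new_m = 2.0 * hyper_upper - new_m
            if 0.0 < new_m <= hyper_upper:
                lpn = _log_prior_rates(rates, new_m)
                if np.log(np.random.random()) < (lpn - lp):
                    m = new_m
                    lp = lpn
                    acc_m += 1
        ll_trace[it] = ll
        if (it + 1) % thin == 0 and rec < n_rec:
            for g in range(n_free):
                samples[rec, g] = rates[g]
            samples[rec, n_free] = m
            rec += 1
    return ll_trace, samples, acc_rate, prop_rate, acc_m, prop_m, rates, m
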