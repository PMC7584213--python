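"""Numeric kernels for the pruning likelihood.

The conditional-likelihood recursion propagates each child vector through
``exp(Q t) v`` using uniformization: with ``mu >= max_i (-Q_ii)`` the matrix
``A = I + Q/mu`` is substochastic with non-negative entries, and

    exp(Q t) v = sum_k Poisson(mu t)_k  A^k v.

The series is truncated when the accumulated Poisson mass exceeds
``1 - 1e-13``; because ``A`` does not increase the sup-norm of non-negative
vectors, the truncated tail bounds the error directly.  Long/fast branches
(``mu t`` large) are split into substeps so the Poisson weights stay in a
numerically safe range.

The generator is passed in dense form and compressed to CSR inside the
kernel; each row has at most five non-zeros (four event classes plus the
diagonal), which keeps every matrix-vector product O(states).
"""

from __future__ import annotations

import numpy as np
from numba import njit

ROOT_FLAT = 0
ROOT_FITZJOHN = 1


@njit(cache=True)
def _dense_to_csr(Q):
    n = Q.shape[0]
    nnz = 0
    for i in range(n):
        for j in range(n):
            if Q[i, j] != 0.0:
                nnz += 1
    indptr = np.empty(n + 1, dtype=np.int64)
    indices = np.empty(nnz, dtype=np.int64)
    data = np.empty(nnz, dtype=np.float64)
    k = 0
    for i in range(n):
        indptr[i] = k
        for j in range(n):
            if Q[i, j] != 0.0:
                indices[k] = j
                data[k] = Q[i, j]
                k += 1
    indptr[n] = k
    return indptr, indices, data


@njit(cache=True)
def _propagate(v, indptr, indices, data, mu, t, term, nxt):
    """exp(Q t) v for a non-negative vector v, via uniformization.

    ``term`` and ``nxt`` are scratch buffers of the same length as ``v``;
    the result is returned in a fresh array."""
    n = v.shape[0]
    out = v.copy()
    if t <= 0.0 or mu <= 0.0:
        return out
    nstep = 1 + int(mu * t / 30.0)
    a = mu * t / nstep
    for _ in range(nstep):
        p = np.exp(-a)
        cum = p
        for i in range(n):
            term[i] = out[i]
            out[i] = p * term[i]
        k = 1
        while cum < 1.0 - 1e-15 and k < 10000:
            for i in range(n):
                s = 0.0
                for idx in range(indptr[i], indptr[i + 1]):
                    s += data[idx] * term[indices[idx]]
                nxt[i] = term[i] + s / mu
            p *= a / k
            cum += p
            for i in range(n):
                term[i] = nxt[i]
                out[i] += p * term[i]
            k += 1
            if p < 1e-20 and k > a:
                break
    for i in range(n):
        if out[i] < 0.0:
            out[i] = 0.0
    return out


@njit(cache=True)
def prune_loglik_kernel(
    postorder,
    children_flat,
    child_start,
    child_count,
    brlen,
    tip_state,
    n_tips,
    Q,
    root_mode,
):
    """Log-likelihood by post-order pruning with per-node rescaling.

    ``tip_state[i]`` is the state index observed at tip ``i``.  Returns
    -inf when the data have probability zero under ``Q``.
    """
    n_states = Q.shape[0]
    n_nodes = postorder.shape[0]
    mu = 0.0
    for i in range(n_states):
        if -Q[i, i] > mu:
            mu = -Q[i, i]
    indptr, indices, data = _dense_to_csr(Q)

    clv = np.zeros((n_nodes, n_states))
    term = np.empty(n_states)
    nxt = np.empty(n_states)
    logscale = 0.0
    for oi in range(n_nodes):
        node = postorder[oi]
        if node < n_tips:
            clv[node, tip_state[node]] = 1.0
            continue
        v = np.ones(n_states)
        for ci in range(child_count[node]):
            child = children_flat[child_start[node] + ci]
            u = _propagate(
                clv[child], indptr, indices, data, mu, brlen[child], term, nxt
            )
            for i in range(n_states):
                v[i] *= u[i]
        m = 0.0
        for i in range(n_states):
            if v[i] > m:
                m = v[i]
        if m <= 0.0:
            return -np.inf
        for i in range(n_states):
            v[i] /= m
        logscale += np.log(m)
        for i in range(n_states):
            clv[node, i] = v[i]

    root = postorder[n_nodes - 1]
    total = 0.0
    for i in range(n_states):
        total += clv[root, i]
    if total <= 0.0:
        return -np.inf
    if root_mode == ROOT_FLAT:
        like = total / n_states
    else:
        ssq = 0.0
        for i in range(n_states):
            ssq += clv[root, i] * clv[root, i]
        like = ssq / total
    if like <= 0.0:
        return -np.inf
    return np.log(like) + logscale


def propagate_uniformized(Q: np.ndarray, t: float, v: np.ndarray) -> np.ndarray:
    """exp(Q t) v via the same kernel the pruning path uses (for checks)."""
    Q = np.ascontiguousarray(Q, dtype=float)
    v = np.ascontiguousarray(v, dtype=float)
    mu = float(np.max(-np.diag(Q))) if Q.size else 0.0
    indptr, indices, data = _dense_to_csr(Q)
    term = np.empty_like(v)
    nxt = np.empty_like(v)
    return _propagate(v, indptr, indices, data, mu, float(t), term, nxt)
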