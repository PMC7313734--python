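"""Numba kernels for the censored-random-walk likelihood.

The list likelihood needs, for every prefix of every list, the probability
that a random walk passing freely through already-produced (visited) items
is first absorbed at the next item.  Each such factor is an absorbing
Markov-chain solve restricted to the visited component of the current node;
the MAP hill-climb re-evaluates it for every candidate edge toggle, so the
inner loop is compiled.

All kernels take a dense 0/1 adjacency matrix (float64) over the
participant vocabulary and lists as int64 index arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _degrees(adj):
    n = adj.shape[0]
    deg = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += adj[i, j]
        deg[i] = s
    return deg


@njit(cache=True)
def first_hit_prob(adj, deg, lst, k):
    """P(walk from lst[k-1], censoring within lst[:k], first hits lst[k]).

    ``lst[:k]`` is the visited (transient) set; all other nodes absorb.  The
    linear system is restricted to the connected component of the current
    node within the visited-induced subgraph; if that component has no edge
    into the unvisited set the continuation is impossible and 0 is returned.
    """
    n = adj.shape[0]
    cur = lst[k - 1]
    target = lst[k]
    # membership flags for the visited prefix
    vis = np.zeros(n, np.bool_)
    for i in range(k):
        vis[lst[i]] = True
    # BFS component of cur within visited nodes
    comp = np.full(n, -1, np.int64)
    order = np.empty(k, np.int64)
    stack = np.empty(k, np.int64)
    comp[cur] = 0
    order[0] = cur
    nc = 1
    sp = 0
    stack[sp] = cur
    sp += 1
    while sp > 0:
        sp -= 1
        v = stack[sp]
        for w in range(n):
            if adj[v, w] > 0.0 and vis[w] and comp[w] < 0:
                comp[w] = nc
                order[nc] = w
                nc += 1
                stack[sp] = w
                sp += 1
    # absorbing-chain system (I - Q) x = b over the component
    A = np.zeros((nc, nc))
    b = np.zeros(nc)
    escape = False
    for ai in range(nc):
        v = order[ai]
        d = deg[v]
        if d == 0.0:
            return 0.0
        inv = 1.0 / d
        A[ai, ai] = 1.0
        for w in range(n):
            if adj[v, w] > 0.0:
                if vis[w]:
                    A[ai, comp[w]] -= inv
                else:
                    escape = True
                    if w == target:
                        b[ai] += inv
    if not escape:
        return 0.0
    x = np.linalg.solve(A, b)
    p = x[0]
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def list_loglik(adj, lst):
    """Log-likelihood of one censored fluency list on a candidate network.

    First item: degree-proportional start.  Subsequent items: first-passage
    probabilities through the growing visited set.  Returns -inf when any
    factor is zero (isolated start, unreachable continuation).
    """
    L = lst.shape[0]
    if L == 0:
        return 0.0
    deg = _degrees(adj)
    total = deg.sum()
    if total == 0.0 or deg[lst[0]] == 0.0:
        return NEG_INF
    ll = np.log(deg[lst[0]] / total)
    for k in range(1, L):
        p = first_hit_prob(adj, deg, lst, k)
        if p <= 0.0:
            return NEG_INF
        ll += np.log(p)
    return ll


@njit(cache=True)
def dataset_loglik(adj, flat, offsets):
    """Sum of list_loglik over lists stored back-to-back in ``flat``.

    ``offsets`` has one more entry than there are lists; list i is
    ``flat[offsets[i]:offsets[i+1]]``.
    """
    out = 0.0
    for i in range(offsets.shape[0] - 1):
        ll = list_loglik(adj, flat[offsets[i] : offsets[i + 1]])
        if ll == NEG_INF:
            return NEG_INF
        out += ll
    return out


@njit(cache=True)
def sweep(adj, flat, offsets, pair_i, pair_j, prior_on, prior_off, cur_ll, cur_lp, tol):
    """One hill-climb sweep over candidate single-edge toggles, in place.

    ``prior_on[i,j]``/``prior_off[i,j]`` are the log prior contributions of
    pair (i,j) being present/absent.  ``cur_ll`` is the current data
    log-likelihood and ``cur_lp`` the current log prior.  A toggle is kept
    iff it raises the log posterior by more than ``tol``.  Returns
    (n_accepted, new_ll, new_lp).
    """
    n_acc = 0
    for idx in range(pair_i.shape[0]):
        i = pair_i[idx]
        j = pair_j[idx]
        old = adj[i, j]
        new = 1.0 - old
        adj[i, j] = new
        adj[j, i] = new
        if new > 0.0:
            d_prior = prior_on[i, j] - prior_off[i, j]
        else:
            d_prior = prior_off[i, j] - prior_on[i, j]
        new_ll = dataset_loglik(adj, flat, offsets)
        if new_ll == NEG_INF or (new_ll - cur_ll) + d_prior <= tol:
            adj[i, j] = old
            adj[j, i] = old
        else:
            cur_ll = new_ll
            cur_lp = cur_lp + d_prior
            n_acc += 1
    return n_acc, cur_ll, cur_lp
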