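"""MAP estimation of individual semantic networks from fluency lists.

The generative model is a censored random walk on an undirected, unweighted
semantic network: the first item is drawn with probability proportional to
its degree, and each later item is the node at which a uniform random walk
(passing silently through already-produced items) first enters the
not-yet-produced set.  The network prior is independent Bernoulli per node
pair, anchored to a reference association network: probability ``p_present``
(default 2/3) for pairs linked in the reference, ``p_absent`` (default 2/5)
for pairs whose nodes are both in the reference but unlinked, and
``p_unknown`` (default 1/2) when either node is missing from the reference.
The estimator is a seeded hill-climb over single-edge toggles that maximizes
the log posterior (likelihood x prior).

Public functions take :class:`networkx.Graph` objects keyed by item labels;
the compiled inner loops (``semfluent._walk``) operate on dense adjacency
matrices over the participant vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import _walk
from .io import FluencyList

__all__ = [
    "PriorSpec",
    "SearchParams",
    "initial_log_probability",
    "first_hit_distribution",
    "list_log_likelihood",
    "dataset_log_likelihood",
    "network_log_prior",
    "log_posterior",
    "build_init_network",
    "estimate_network",
]


@dataclass(frozen=True)
class PriorSpec:
    """Bernoulli edge prior anchored to a reference association network."""

    reference: nx.Graph
    p_present: float = 2.0 / 3.0
    p_absent: float = 2.0 / 5.0
    p_unknown: float = 1.0 / 2.0

    def __post_init__(self) -> None:
        for name in ("p_present", "p_absent", "p_unknown"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p}")

    def edge_probability(self, u: str, v: str) -> float:
        """Prior probability that the unordered pair (u, v) is an edge."""
        ref = self.reference
        if u in ref and v in ref:
            return self.p_present if ref.has_edge(u, v) else self.p_absent
        return self.p_unknown


@dataclass(frozen=True)
class SearchParams:
    """Hill-climb schedule for the MAP search."""

    seed: int
    max_sweeps: int = 100
    tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


def _adjacency(network: nx.Graph, vocab: Sequence[str]) -> np.ndarray:
    index = {v: i for i, v in enumerate(vocab)}
    adj = np.zeros((len(vocab), len(vocab)))
    for a, b in network.edges:
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = 1.0
    return adj


def initial_log_probability(network: nx.Graph, item: str) -> float:
    """Log probability that ``item`` starts a list: log(deg / sum of degrees)."""
    if item not in network:
        raise KeyError(f"{item!r} is not a node of the network")
    total = 2 * network.number_of_edges()
    if total == 0:
        raise ValueError("network has no edges")
    d = network.degree(item)
    if d == 0:
        return -math.inf
    return math.log(d / total)


def first_hit_distribution(
    network: nx.Graph, visited: Sequence[str], current: str
) -> dict[str, float]:
    """First-passage probabilities into each unvisited node.

    For a walk at ``current`` that moves uniformly over neighbors and passes
    freely through ``visited`` nodes, returns for each unvisited node u the
    probability of first entering the unvisited set at u.  Computed by a
    dense linear solve of the absorbing-chain system (I - T_VV) X = T_VU
    restricted to the visited component of ``current``; this is the
    pure-numpy mirror of the compiled kernel used during estimation.

    If the visited component of ``current`` has no edge into the unvisited
    set (an impossible continuation) the all-zero map is returned.
    """
    if current not in visited:
        raise ValueError("current must be among the visited nodes")
    for v in visited:
        if v not in network:
            raise KeyError(f"visited node {v!r} is not in the network")
        if network.degree(v) == 0:
            raise ValueError(f"visited node {v!r} has degree 0")
    vis = set(visited)
    unvisited = [u for u in network.nodes if u not in vis]
    zero = {u: 0.0 for u in unvisited}
    # visited component of current
    comp: list[str] = [current]
    seen = {current}
    queue = [current]
    while queue:
        v = queue.pop()
        for w in network.neighbors(v):
            if w in vis and w not in seen:
                seen.add(w)
                comp.append(w)
                queue.append(w)
    cindex = {v: i for i, v in enumerate(comp)}
    uindex = {u: i for i, u in enumerate(unvisited)}
    m, nu = len(comp), len(unvisited)
    A = np.eye(m)
    B = np.zeros((m, nu))
    escape = False
    for v in comp:
        inv = 1.0 / network.degree(v)
        for w in network.neighbors(v):
            if w in vis:
                A[cindex[v], cindex[w]] -= inv
            else:
                escape = True
                B[cindex[v], uindex[w]] += inv
    if not escape:
        return zero
    X = np.linalg.solve(A, B)
    row = np.clip(X[cindex[current]], 0.0, 1.0)
    return {u: float(row[uindex[u]]) for u in unvisited}


def _as_indices(items: Sequence[str], index: Mapping[str, int]) -> np.ndarray:
    try:
        return np.array([index[x] for x in items], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"list item {exc.args[0]!r} is not a node of the network") from None


def list_log_likelihood(network: nx.Graph, fluency_list: FluencyList | Sequence[str]) -> float:
    """Log probability of one censored fluency list under the walk model.

    Lists are treated as time-limited prefixes: stopping carries no
    probability penalty.  Returns -inf when the list cannot be produced
    (isolated start or unreachable continuation); raises KeyError when an
    item is not a node at all (vocabulary mismatch).
    """
    items = fluency_list.items if isinstance(fluency_list, FluencyList) else tuple(fluency_list)
    vocab = sorted(network.nodes)
    index = {v: i for i, v in enumerate(vocab)}
    lst = _as_indices(items, index)
    return float(_walk.list_loglik(_adjacency(network, vocab), lst))


def dataset_log_likelihood(
    network: nx.Graph, lists: Sequence[FluencyList | Sequence[str]]
) -> float:
    """Sum of list log-likelihoods: lists are independent restarts."""
    return float(sum(list_log_likelihood(network, fl) for fl in lists))


def network_log_prior(network: nx.Graph, prior: PriorSpec) -> float:
    """Log Bernoulli prior over all unordered node pairs of the network."""
    vocab = sorted(network.nodes)
    lp = 0.0
    for i, u in enumerate(vocab):
        for v in vocab[i + 1 :]:
            p = prior.edge_probability(u, v)
            lp += math.log(p) if network.has_edge(u, v) else math.log1p(-p)
    return lp


def log_posterior(
    network: nx.Graph,
    lists: Sequence[FluencyList | Sequence[str]],
    prior: PriorSpec,
) -> float:
    """Unnormalized log posterior: data log-likelihood + network log prior."""
    ll = dataset_log_likelihood(network, lists)
    if ll == -math.inf:
        return -math.inf
    return ll + network_log_prior(network, prior)


def build_init_network(lists: Sequence[FluencyList | Sequence[str]]) -> nx.Graph:
    """Consecutive-adjacency starting network.

    Nodes are the union of produced items; an edge joins every pair of items
    adjacent in at least one list.  Every observed transition is then an
    edge, so the data log-likelihood is finite.
    """
    g = nx.Graph()
    for fl in lists:
        items = fl.items if isinstance(fl, FluencyList) else tuple(fl)
        g.add_nodes_from(items)
        g.add_edges_from(zip(items, items[1:]))
    return g


def estimate_network(
    lists: Sequence[FluencyList | Sequence[str]],
    prior: PriorSpec,
    params: SearchParams,
) -> tuple[nx.Graph, float, list[dict]]:
    """Seeded hill-climb for the MAP network of one participant.

    Starting from the consecutive-adjacency graph, candidate single-edge
    toggles over all vocabulary pairs are swept in seeded-random order; a
    toggle is kept iff it raises the log posterior by more than the
    tolerance.  Stops after a full acceptance-free sweep or ``max_sweeps``.
    Returns (network, final log posterior, per-sweep trace); deterministic
    given the seed.
    """
    item_lists = [
        fl.items if isinstance(fl, FluencyList) else tuple(fl) for fl in lists
    ]
    item_lists = [items for items in item_lists if items]
    if not item_lists:
        raise ValueError("no nonempty fluency lists to estimate from")
    vocab = sorted(set().union(*item_lists))
    if not vocab:
        raise ValueError("empty vocabulary")
    index = {v: i for i, v in enumerate(vocab)}
    n = len(vocab)

    init = build_init_network(item_lists)
    adj = _adjacency(init, vocab)

    flat = np.concatenate([_as_indices(items, index) for items in item_lists])
    offsets = np.cumsum([0] + [len(items) for items in item_lists]).astype(np.int64)

    # per-pair log prior contributions, precomputed once
    prior_on = np.zeros((n, n))
    prior_off = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = prior.edge_probability(vocab[i], vocab[j])
            prior_on[i, j] = prior_on[j, i] = math.log(p)
            prior_off[i, j] = prior_off[j, i] = math.log1p(-p)

    iu, ju = np.triu_indices(n, k=1)
    cur_ll = float(_walk.dataset_loglik(adj, flat, offsets))
    cur_lp = float(
        np.where(adj[iu, ju] > 0, prior_on[iu, ju], prior_off[iu, ju]).sum()
    )

    rng = np.random.default_rng(params.seed)
    trace: list[dict] = []
    for sweep_no in range(params.max_sweeps):
        order = rng.permutation(iu.shape[0])
        n_acc, cur_ll, cur_lp = _walk.sweep(
            adj,
            flat,
            offsets,
            iu[order].astype(np.int64),
            ju[order].astype(np.int64),
            prior_on,
            prior_off,
            cur_ll,
            cur_lp,
            params.tolerance,
        )
        trace.append(
            {"sweep": sweep_no, "accepted": int(n_acc), "log_posterior": cur_ll + cur_lp}
        )
        if n_acc == 0:
            break

    result = nx.Graph()
    result.add_nodes_from(vocab)
    ii, jj = np.nonzero(np.triu(adj))
    result.add_edges_from((vocab[a], vocab[b]) for a, b in zip(ii, jj))
    return result, cur_ll + cur_lp, trace
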