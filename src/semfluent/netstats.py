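"""Graph statistics for estimated semantic networks.

ASPL and the small-world index follow the largest-component convention
(disconnected networks are reduced to their largest connected component
first); average local clustering and modularity are computed on the full
graph.  The small-world index is the Humphries & Gurney sigma,
(C/C_rand)/(L/L_rand), against Erdos-Renyi G(n, m) null graphs with matched
node and edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

__all__ = [
    "MetricSettings",
    "NetworkMetrics",
    "largest_component",
    "aspl",
    "avg_clustering",
    "modularity_best",
    "small_world_sigma",
    "compute_all",
]


@dataclass(frozen=True)
class MetricSettings:
    seed: int = 0
    modularity_restarts: int = 10
    n_random: int = 100           # small-world null replicates
    clustering: str = "average"   # or "transitivity"
    sigma_retry_cap: int = 200


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    n_components: int
    lcc_size: int
    aspl: float
    clustering: float
    modularity: float
    small_world: float

    def as_dict(self) -> dict:
        return asdict(self)


def largest_component(network: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties break toward the component containing the lexicographically
    smallest member node, so the reduction is deterministic.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(network))
    biggest = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == biggest), key=lambda c: min(map(str, c)))
    return network.subgraph(best).copy()


def aspl(network: nx.Graph) -> float:
    """Mean unweighted shortest-path length over unordered node pairs."""
    if not nx.is_connected(network):
        raise ValueError("aspl requires a connected graph; reduce to the largest component first")
    return float(nx.average_shortest_path_length(network))


def avg_clustering(network: nx.Graph, variant: str = "average") -> float:
    """Average local clustering (default) or global transitivity."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    if variant == "average":
        return float(nx.average_clustering(network, count_zeros=True))
    if variant == "transitivity":
        return float(nx.transitivity(network))
    raise ValueError(f"unknown clustering variant {variant!r}")


def modularity_best(
    network: nx.Graph, restarts: int = 10, seed: int = 0
) -> tuple[float, list[set]]:
    """Best Newman-Girvan modularity over seeded Louvain restarts.

    The single-community partition (Q = 0) is always a candidate, so the
    returned Q is never negative.  Deterministic given (seed, restarts).
    """
    if network.number_of_edges() == 0:
        raise ValueError("modularity requires at least one edge")
    best_q = 0.0
    best_part: list[set] = [set(network.nodes)]
    for r in range(restarts):
        part = nx.community.louvain_communities(network, seed=seed * 7919 + r)
        q = nx.community.modularity(network, part)
        if q > best_q:
            best_q, best_part = q, [set(c) for c in part]
    return float(best_q), best_part


def small_world_sigma(
    network: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    retry_cap: int = 200,
) -> float:
    """Humphries & Gurney small-world sigma against G(n, m) null graphs.

    sigma = (C / mean C_rand) / (L / mean L_rand) where the means are over
    ``n_random`` Erdos-Renyi graphs with the observed node and edge counts;
    each replicate uses its largest component when disconnected.  Replicates
    with zero clustering (which would make the ratio undefined) are redrawn,
    up to ``retry_cap`` total redraws.
    """
    n = network.number_of_nodes()
    m = network.number_of_edges()
    if n < 4 or m < 3:
        raise ValueError(f"small-world sigma needs >= 4 nodes and >= 3 edges, got n={n}, m={m}")
    if not nx.is_connected(network):
        raise ValueError("pass the largest component to small_world_sigma")
    c_obs = avg_clustering(network)
    l_obs = aspl(network)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    retries = 0
    i = 0
    while i < n_random:
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        g = largest_component(g)
        c = avg_clustering(g)
        if c == 0.0 or g.number_of_nodes() < 2:
            retries += 1
            if retries > retry_cap:
                raise ValueError(
                    f"could not draw {n_random} usable null graphs for n={n}, m={m}: "
                    f"replicates keep degenerating to zero clustering"
                )
            continue
        c_rand[i] = c
        l_rand[i] = aspl(g)
        i += 1
    return float((c_obs / c_rand.mean()) / (l_obs / l_rand.mean()))


def compute_all(network: nx.Graph, settings: MetricSettings = MetricSettings()) -> NetworkMetrics:
    """All metrics for one network under the stated component conventions."""
    lcc = largest_component(network)
    return NetworkMetrics(
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        n_components=nx.number_connected_components(network),
        lcc_size=lcc.number_of_nodes(),
        aspl=aspl(lcc) if lcc.number_of_nodes() >= 2 else float("nan"),
        clustering=avg_clustering(network, settings.clustering),
        modularity=modularity_best(network, settings.modularity_restarts, settings.seed)[0],
        small_world=small_world_sigma(
            lcc, settings.n_random, settings.seed, settings.sigma_retry_cap
        ),
    )
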