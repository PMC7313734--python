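"""Synthetic-cohort generator.

Emulates the study design the analysis pipeline assumes: three groups
(monolingual n=25, English-Spanish bilingual n=13, Spanish-English bilingual
n=28), three animal-fluency lists per participant produced by a censored
random walk on a participant-specific ground-truth network, sparse intrusion
and perseveration noise, and per-participant creativity and intelligence
scores whose population correlations with the realized network statistics
are dialed by a Gaussian copula (all zero in the default null world, with
an intelligence-creativity correlation of 0.185).

Every output is reproducible bit-for-bit from ``master_seed``: participant
i's lists derive from ``SeedSequence([master_seed, i])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import bundled_lexicon
from .netstats import MetricSettings, compute_all

__all__ = [
    "CohortConfig",
    "make_reference_network",
    "perturb_network",
    "simulate_list",
    "simulate_cohort",
]

GROUPS = ("monolingual", "ES", "SE")

# out-of-category tokens used as intrusions
INTRUSION_POOL = (
    "house", "unicorn", "car", "table", "dragon", "mermaid",
    "tree", "chair", "rock", "cloud", "phone", "goblin",
)

METRIC_KEYS = ("aspl", "clustering", "modularity", "small_world", "mean_items")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reproduce the study's design conditions."""

    n_monolingual: int = 25
    n_es: int = 13
    n_se: int = 28
    lists_per_participant: int = 3
    # per-group mean list length; SE bilinguals perform in their L2
    list_length_mean: dict = field(
        default_factory=lambda: {"monolingual": 42.1, "ES": 42.1, "SE": 33.3}
    )
    list_length_sd: float = 6.5
    min_list_length: int = 5
    intrusion_rate: float = 0.005
    perseveration_rate: float = 0.015
    creativity_mean: dict = field(
        default_factory=lambda: {"monolingual": 15.6, "ES": 14.5, "SE": 16.7}
    )
    creativity_sd: float = 6.5
    intelligence_mean: float = 8.0
    intelligence_sd: float = 2.0
    # population correlations of creativity with intelligence and with the
    # realized per-participant statistics; the default is the null world
    target_correlations: dict = field(
        default_factory=lambda: {
            "intelligence": 0.185,
            "mean_items": 0.0,
            "aspl": 0.0,
            "clustering": 0.0,
            "modularity": 0.0,
            "small_world": 0.0,
        }
    )
    # shared reference network and participant-level deviation from it
    ref_n_nodes: int = 60
    ref_n_edges: int = 240
    ref_model: str = "random"
    p_drop: float = 0.2
    p_add: float | None = None  # None: density-preserving expected edge count
    truth_metric_n_random: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_monolingual, self.n_es, self.n_se) < 1:
            raise ValueError("all group sizes must be >= 1")
        for rate in (self.intrusion_rate, self.perseveration_rate):
            if not 0 <= rate < 1:
                raise ValueError("noise rates must be in [0, 1)")
        rho = self.target_correlations
        if any(abs(v) >= 1 for v in rho.values()):
            raise ValueError("target correlations must have |rho| < 1")
        ss = sum(rho[k] ** 2 for k in METRIC_KEYS)
        if ss >= 1.0:
            raise ValueError(
                "infeasible target correlations: sum of squared metric "
                f"correlations is {ss:.3f} >= 1"
            )

    def group_sizes(self) -> dict[str, int]:
        return {"monolingual": self.n_monolingual, "ES": self.n_es, "SE": self.n_se}


def _repair_connectivity(g: nx.Graph) -> int:
    """Join components with bridge edges between their smallest nodes."""
    n_added = 0
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    while len(comps) > 1:
        a = comps[0][0]
        b = comps[1][0]
        g.add_edge(a, b)
        comps = [sorted(set(comps[0]) | set(comps[1]))] + comps[2:]
        n_added += 1
    return n_added


def make_reference_network(
    n_nodes: int,
    model: str = "random",
    params: dict | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Connected labeled network over toy animal names; deterministic per seed.

    Models: ``random`` (G(n, m)), ``ring_lattice_rewired`` (Watts-Strogatz),
    ``communities`` (planted partition).  Draws that come out disconnected
    are repaired with minimal bridge edges; the number added is recorded in
    ``g.graph["n_repair_edges"]``.
    """
    params = dict(params or {})
    labels = sorted(bundled_lexicon())
    if n_nodes > len(labels):
        raise ValueError(
            f"n_nodes={n_nodes} exceeds the bundled lexicon size {len(labels)}"
        )
    if model == "random":
        m = int(params.get("n_edges", 4 * n_nodes))
        g = nx.gnm_random_graph(n_nodes, m, seed=seed)
    elif model == "ring_lattice_rewired":
        k = int(params.get("k", 6))
        p = float(params.get("p", 0.1))
        g = nx.watts_strogatz_graph(n_nodes, k, p, seed=seed)
    elif model == "communities":
        blocks = int(params.get("blocks", 2))
        p_in = float(params.get("p_in", 0.4))
        p_out = float(params.get("p_out", 0.02))
        g = nx.planted_partition_graph(blocks, n_nodes // blocks, p_in, p_out, seed=seed)
        g = nx.Graph(g)  # drop multigraph/self-loop artifacts of the generator
        g.remove_edges_from(nx.selfloop_edges(g))
    else:
        raise ValueError(f"unknown reference model {model!r}")
    n_added = _repair_connectivity(g)
    g = nx.relabel_nodes(g, {i: labels[i] for i in g.nodes})
    g.graph["n_repair_edges"] = n_added
    return g


def perturb_network(
    reference: nx.Graph, p_drop: float, p_add: float, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Individual deviation from the shared reference network.

    Each reference edge is kept with probability 1 - p_drop; each non-edge
    is added with probability p_add.  Node set preserved.
    """
    if not (0 <= p_drop <= 1 and 0 <= p_add <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = sorted(reference.nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if reference.has_edge(u, v):
                if rng.random() >= p_drop:
                    g.add_edge(u, v)
            elif p_add > 0 and rng.random() < p_add:
                g.add_edge(u, v)
    return g


def simulate_list(
    network: nx.Graph,
    length: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    _max_steps_factor: int = 2000,
) -> list[str]:
    """One censored-random-walk fluency list of ``length`` distinct items.

    The first item is drawn degree-proportionally; each step moves uniformly
    over neighbors; only first visits are emitted.  Raises when the
    connected component containing the start has fewer than ``length``
    nodes.  Deterministic per seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    deg = np.array([network.degree(v) for v in nodes], dtype=float)
    total = deg.sum()
    if total == 0:
        raise ValueError("network has no edges")
    start = nodes[rng.choice(len(nodes), p=deg / total)]
    comp = nx.node_connected_component(network, start)
    if len(comp) < length:
        raise ValueError(
            f"component of start node {start!r} has {len(comp)} nodes < length {length}"
        )
    neighbors = {v: sorted(network.neighbors(v)) for v in comp}
    out = [start]
    emitted = {start}
    cur = start
    max_steps = _max_steps_factor * max(length, len(comp))
    for _ in range(max_steps):
        if len(out) >= length:
            return out
        cur = neighbors[cur][rng.integers(len(neighbors[cur]))]
        if cur not in emitted:
            emitted.add(cur)
            out.append(cur)
    raise RuntimeError("walk failed to cover the requested length within the step cap")


def _rank_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom-style offsets)."""
    ranks = pd.Series(x).rank(method="average").to_numpy()
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def _inject_noise(
    items: list[str], rng: np.random.Generator, intrusion_rate: float, pers_rate: float
) -> list[str]:
    raw: list[str] = []
    for item in items:
        raw.append(item)
        if len(raw) > 1 and rng.random() < pers_rate:
            raw.append(raw[rng.integers(len(raw) - 1)])
        if rng.random() < intrusion_rate:
            raw.append(INTRUSION_POOL[rng.integers(len(INTRUSION_POOL))])
    return raw


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full cohort: raw fluency table, score table, truth registry.

    Returns ``(fluency_table, score_table, registry)`` where the registry
    maps participant ids to their group, ground-truth edge list, list seed,
    and realized statistics, plus the shared reference edge list.
    """
    ref_rng_seed = int(np.random.SeedSequence([config.master_seed, 0]).generate_state(1)[0] % (2**31))
    reference = make_reference_network(
        config.ref_n_nodes, config.ref_model, {"n_edges": config.ref_n_edges},
        seed=ref_rng_seed,
    )
    n_ref_edges = reference.number_of_edges()
    n_pairs = config.ref_n_nodes * (config.ref_n_nodes - 1) // 2
    if config.p_add is None:
        p_add = config.p_drop * n_ref_edges / max(n_pairs - n_ref_edges, 1)
    else:
        p_add = config.p_add

    rows = []
    registry: dict = {
        "reference_edges": sorted(tuple(sorted(e)) for e in reference.edges),
        "participants": {},
    }
    realized: dict[str, list[float]] = {k: [] for k in METRIC_KEYS}
    pids: list[str] = []
    groups: list[str] = []

    idx = 0
    for group in GROUPS:
        for _ in range(config.group_sizes()[group]):
            idx += 1
            pid = f"p{idx:03d}"
            prng = np.random.default_rng(np.random.SeedSequence([config.master_seed, idx]))
            truth = perturb_network(reference, config.p_drop, p_add, rng=prng)
            lcc_size = max(len(c) for c in nx.connected_components(truth))
            clean_lengths = []
            for ln in range(config.lists_per_participant):
                length = int(round(prng.normal(
                    config.list_length_mean[group], config.list_length_sd
                )))
                length = max(config.min_list_length, min(length, lcc_size))
                for attempt in range(200):
                    try:
                        items = simulate_list(truth, length, rng=prng)
                        break
                    except ValueError:
                        continue  # start landed in a too-small component; redraw
                else:
                    raise RuntimeError(f"could not simulate a list for {pid}")
                clean_lengths.append(len(items))
                raw = _inject_noise(
                    items, prng, config.intrusion_rate, config.perseveration_rate
                )
                rows.extend(
                    {"id": pid, "listnum": ln, "position": pos, "item": item}
                    for pos, item in enumerate(raw)
                )
            metrics = compute_all(
                truth,
                MetricSettings(
                    seed=int(prng.integers(2**31 - 1)),
                    modularity_restarts=5,
                    n_random=config.truth_metric_n_random,
                ),
            )
            mean_items = sum(clean_lengths) / len(clean_lengths)
            for key in METRIC_KEYS:
                realized[key].append(
                    mean_items if key == "mean_items" else getattr(metrics, key)
                )
            registry["participants"][pid] = {
                "group": group,
                "seed_key": [config.master_seed, idx],
                "truth_edges": sorted(tuple(sorted(e)) for e in truth.edges),
                "realized": {
                    k: realized[k][-1] for k in METRIC_KEYS
                },
            }
            pids.append(pid)
            groups.append(group)

    fluency = pd.DataFrame(rows, columns=["id", "listnum", "position", "item"])
    scores = _draw_scores(config, pids, groups, realized)
    return fluency, scores, registry


def _draw_scores(
    config: CohortConfig,
    pids: list[str],
    groups: list[str],
    realized: dict[str, list[float]],
) -> pd.DataFrame:
    """Creativity and intelligence via a Gaussian copula on realized statistics."""
    n = len(pids)
    rho = config.target_correlations
    srng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 10**6]))

    X = np.column_stack([_rank_normal(np.asarray(realized[k])) for k in METRIC_KEYS])
    S = np.corrcoef(X, rowvar=False) + 1e-8 * np.eye(len(METRIC_KEYS))
    rho_vec = np.array([rho[k] for k in METRIC_KEYS])
    w = np.linalg.solve(S, rho_vec)
    var_expl = float(rho_vec @ w)
    if var_expl >= 1.0:
        raise ValueError(
            "target correlations infeasible given the realized statistics' "
            f"own correlation structure (explained variance {var_expl:.3f} >= 1)"
        )
    z_c = X @ w + math.sqrt(1.0 - var_expl) * srng.standard_normal(n)

    r_ci = rho["intelligence"]
    z_i = r_ci * z_c + math.sqrt(1.0 - r_ci**2) * srng.standard_normal(n)

    creativity = []
    for i, g in enumerate(groups):
        c = config.creativity_mean[g] + config.creativity_sd * z_c[i]
        creativity.append(int(round(max(c, 0.0))))
    intelligence = [
        int(round(min(max(config.intelligence_mean + config.intelligence_sd * z, 0.0), 12.0)))
        for z in z_i
    ]
    return pd.DataFrame(
        {"id": pids, "group": groups, "creativity": creativity, "intelligence": intelligence}
    ).set_index("id")
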