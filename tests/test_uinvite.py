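"""Censored-random-walk likelihood, edge prior, and MAP search."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from semfluent import uinvite as uv
from semfluent.synthetic import make_reference_network, simulate_list


def neumann_list_logprob(network, items, tol=1e-10, max_len=20000):
    """Independent oracle: censored-list probability as an explicit sum over
    walks of bounded length (truncated Neumann series with a tail bound).

    For each transition, sums Q^l R over walk lengths l = 0..L where Q holds
    within-visited steps and R the absorbing step, stopping once the
    remaining transient mass from the current node is below ``tol``.
    """
    nodes = sorted(network.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    deg = np.array([network.degree(v) for v in nodes], float)
    if deg.sum() == 0 or deg[index[items[0]]] == 0:
        return -math.inf
    logp = math.log(deg[index[items[0]]] / deg.sum())
    n = len(nodes)
    T = np.zeros((n, n))
    for i, v in enumerate(nodes):
        for w in network.neighbors(v):
            T[i, index[w]] = 1.0 / deg[i]
    for k in range(1, len(items)):
        vis = [index[x] for x in items[:k]]
        unv = [i for i in range(n) if i not in vis]
        cur = index[items[k - 1]]
        tgt = index[items[k]]
        Q = T[np.ix_(vis, vis)]
        r = T[np.ix_(vis, [tgt])][:, 0]
        e = np.zeros(len(vis))
        e[vis.index(cur)] = 1.0
        total = 0.0
        row = e
        for _ in range(max_len):
            total += row @ r
            row = row @ Q
            if row.sum() < tol:  # bound on all remaining walk probability
                break
        if total <= 0:
            return -math.inf
        logp += math.log(total)
    return logp


class TestInitialLogProbability:
    def test_triangle_symmetry(self, triangle):
        for v in "abc":
            assert uv.initial_log_probability(triangle, v) == pytest.approx(math.log(1 / 3))

    def test_path_degrees(self, path3):
        assert uv.initial_log_probability(path3, "b") == pytest.approx(math.log(1 / 2))
        assert uv.initial_log_probability(path3, "a") == pytest.approx(math.log(1 / 4))

    def test_isolated_node(self, path3):
        path3.add_node("d")
        assert uv.initial_log_probability(path3, "d") == -math.inf

    def test_unknown_item(self, path3):
        with pytest.raises(KeyError):
            uv.initial_log_probability(path3, "zebra")


class TestFirstHitDistribution:
    def test_cycle_hand_solution(self, cycle4):
        # p_b = 1/2 + (1/2) p_a, p_a = (1/2) p_b  =>  p_b(c) = 2/3
        dist = uv.first_hit_distribution(cycle4, ["a", "b"], "b")
        assert dist["c"] == pytest.approx(2 / 3)
        assert dist["d"] == pytest.approx(1 / 3)

    def test_star_symmetry(self):
        star = nx.star_graph(["s", "l1", "l2", "l3"])
        dist = uv.first_hit_distribution(star, ["l1", "s"], "s")
        assert dist["l2"] == pytest.approx(1 / 2)
        assert dist["l3"] == pytest.approx(1 / 2)

    def test_single_neighbor(self, path3):
        assert uv.first_hit_distribution(path3, ["a"], "a") == {"b": 1.0, "c": 0.0}

    def test_trapped_walk_returns_zero_map(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        dist = uv.first_hit_distribution(g, ["a", "b"], "b")
        assert all(p == 0.0 for p in dist.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_probabilities_sum_to_absorption_mass(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(7, 10, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nodes = [v for v in sorted(g.nodes) if g.degree(v) > 0]
        k = int(rng.integers(1, max(2, len(nodes) - 1)))
        visited = list(rng.permutation(nodes))[:k]
        dist = uv.first_hit_distribution(g, visited, visited[-1])
        assert all(0.0 <= p <= 1.0 for p in dist.values())
        total = sum(dist.values())
        reachable = any(
            w not in set(visited)
            for v in nx.node_connected_component(
                g.subgraph([x for x in g if x in set(visited)]), visited[-1]
            )
            for w in g.neighbors(v)
        )
        if reachable:
            assert total == pytest.approx(1.0)
        else:
            assert total == 0.0


class TestListLogLikelihood:
    def test_path_two_items(self, path3):
        assert uv.list_log_likelihood(path3, ["a", "b"]) == pytest.approx(math.log(1 / 4))

    def test_triangle_three_items(self, triangle):
        # brute-force over censored walks on K3: 1/3 * 1/2 * 1
        assert uv.list_log_likelihood(triangle, ["a", "b", "c"]) == pytest.approx(
            math.log(1 / 6)
        )

    def test_unreachable_is_minus_inf(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert uv.list_log_likelihood(g, ["a", "c"]) == -math.inf

    def test_vocabulary_mismatch_raises(self, path3):
        with pytest.raises(KeyError):
            uv.list_log_likelihood(path3, ["a", "zebra"])

    def test_matches_walk_enumeration_oracle(self):
        # all non-isomorphic graphs on <= 5 nodes with at least one edge
        from networkx.generators.atlas import graph_atlas_g

        rng = np.random.default_rng(0)
        checked = 0
        for g in graph_atlas_g()[1:53]:
            if g.number_of_edges() == 0:
                continue
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            nodes = [v for v in sorted(g.nodes) if g.degree(v) > 0]
            for _ in range(2):
                perm = list(rng.permutation(nodes))
                expected = neumann_list_logprob(g, perm)
                got = uv.list_log_likelihood(g, perm)
                if math.isinf(expected):
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-6)
                checked += 1
        assert checked > 50


class TestDatasetLogLikelihood:
    def test_additivity(self, path3):
        ll = uv.dataset_log_likelihood(path3, [["a", "b"], ["a", "b"]])
        assert ll == pytest.approx(2 * math.log(1 / 4))

    def test_empty_collection(self, path3):
        assert uv.dataset_log_likelihood(path3, []) == 0.0

    def test_absorbing_zero(self, path3):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert uv.dataset_log_likelihood(g, [["a", "b"], ["a", "c"]]) == -math.inf


@pytest.fixture
def xyz_prior():
    ref = nx.Graph()
    ref.add_edge("x", "y")
    return uv.PriorSpec(ref)


class TestNetworkLogPrior:
    def test_printed_parameters(self, xyz_prior):
        g = nx.Graph()
        g.add_nodes_from("xyz")
        g.add_edge("x", "y")
        assert uv.network_log_prior(g, xyz_prior) == pytest.approx(math.log(2 / 3 / 4))

    def test_empty_graph(self, xyz_prior):
        g = nx.Graph()
        g.add_nodes_from("xyz")
        assert uv.network_log_prior(g, xyz_prior) == pytest.approx(math.log(1 / 3 / 4))

    @pytest.mark.parametrize("n", [3, 4])
    def test_normalization(self, xyz_prior, n):
        nodes = ["x", "y", "z", "w"][:n]
        pairs = list(itertools.combinations(nodes, 2))
        total = 0.0
        for k in range(len(pairs) + 1):
            for edges in itertools.combinations(pairs, k):
                g = nx.Graph()
                g.add_nodes_from(nodes)
                g.add_edges_from(edges)
                total += math.exp(uv.network_log_prior(g, xyz_prior))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            uv.PriorSpec(nx.Graph(), p_present=1.0)


def test_log_posterior_is_sum(path3, xyz_prior):
    lists = [["a", "b"]]
    prior = uv.PriorSpec(nx.Graph([("a", "b")]))
    assert uv.log_posterior(path3, lists, prior) == pytest.approx(
        uv.dataset_log_likelihood(path3, lists) + uv.network_log_prior(path3, prior)
    )


class TestBuildInitNetwork:
    def test_consecutive_adjacency(self):
        g = uv.build_init_network([["a", "b", "c"]])
        assert {frozenset(e) for e in g.edges} == {frozenset("ab"), frozenset("bc")}

    def test_undirected_merge(self):
        g = uv.build_init_network([["a", "b"], ["b", "a"]])
        assert g.number_of_edges() == 1

    def test_init_likelihood_finite(self):
        lists = [["a", "b", "c", "d"], ["d", "c", "a", "b"]]
        g = uv.build_init_network(lists)
        assert uv.dataset_log_likelihood(g, lists) > -math.inf


class TestEstimateNetwork:
    def test_forced_edge_retained(self):
        prior = uv.PriorSpec(nx.Graph())
        net, lp, _ = uv.estimate_network(
            [["a", "b"]] * 3, prior, uv.SearchParams(seed=0, max_sweeps=5)
        )
        assert net.has_edge("a", "b")
        assert lp > -math.inf

    def test_hill_climb_never_worse_than_init(self):
        truth = make_reference_network(8, "random", {"n_edges": 14}, seed=5)
        lists = [simulate_list(truth, 8, seed=100 + i) for i in range(12)]
        prior = uv.PriorSpec(truth)
        init = uv.build_init_network(lists)
        net, lp, trace = uv.estimate_network(lists, prior, uv.SearchParams(seed=1))
        assert lp >= uv.log_posterior(init, lists, prior)
        assert trace[-1]["accepted"] == 0 or len(trace) == 100

    def test_deterministic_given_seed(self):
        truth = make_reference_network(6, "random", {"n_edges": 9}, seed=2)
        lists = [simulate_list(truth, 6, seed=i) for i in range(5)]
        prior = uv.PriorSpec(truth)
        a = uv.estimate_network(lists, prior, uv.SearchParams(seed=3))
        b = uv.estimate_network(lists, prior, uv.SearchParams(seed=3))
        assert set(a[0].edges) == set(b[0].edges)
        assert a[1] == b[1]

    def test_relabel_invariance(self):
        # order-preserving relabeling keeps the seeded proposal order aligned
        truth = make_reference_network(6, "random", {"n_edges": 9}, seed=4)
        lists = [simulate_list(truth, 6, seed=i) for i in range(5)]
        mapping = {v: v + v for v in truth.nodes}  # 'cat' -> 'catcat', keeps sort order
        truth2 = nx.relabel_nodes(truth, mapping)
        lists2 = [[mapping[x] for x in lst] for lst in lists]
        a, lp_a, _ = uv.estimate_network(lists, uv.PriorSpec(truth), uv.SearchParams(seed=5))
        b, lp_b, _ = uv.estimate_network(lists2, uv.PriorSpec(truth2), uv.SearchParams(seed=5))
        assert {frozenset((mapping[u], mapping[v])) for u, v in a.edges} == {
            frozenset(e) for e in b.edges
        }
        assert lp_a == pytest.approx(lp_b)

    def test_recovery_beats_trivial_graphs(self):
        truth = make_reference_network(8, "random", {"n_edges": 14}, seed=9)
        lists = [simulate_list(truth, 8, seed=500 + i) for i in range(50)]
        net, _, _ = uv.estimate_network(
            lists, uv.PriorSpec(truth), uv.SearchParams(seed=2)
        )

        def f1(g):
            tp = {frozenset(e) for e in truth.edges}
            ep = {frozenset(e) for e in g.edges}
            if not ep:
                return 0.0
            prec = len(tp & ep) / len(ep)
            rec = len(tp & ep) / len(tp)
            return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

        complete = nx.complete_graph(truth.nodes)
        assert f1(net) >= f1(nx.empty_graph(truth.nodes))
        assert f1(net) >= f1(complete)

    def test_empty_vocabulary_errors(self):
        with pytest.raises(ValueError):
            uv.estimate_network([], uv.PriorSpec(nx.Graph()), uv.SearchParams(seed=0))
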