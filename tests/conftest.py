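import networkx as nx
import pytest


@pytest.fixture
def path3():
    """Path graph a - b - c."""
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle():
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def cycle4():
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def two_triangle_bridge():
    """Two triangles joined by a single bridge edge."""
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("c", "a"),
         ("d", "e"), ("e", "f"), ("f", "d"),
         ("a", "d")]
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast synthetic cohort shared across pipeline tests."""
    from semfluent.synthetic import CohortConfig, simulate_cohort

    config = CohortConfig(
        n_monolingual=4, n_es=3, n_se=4,
        list_length_mean={"monolingual": 11.0, "ES": 11.0, "SE": 8.0},
        list_length_sd=2.0,
        ref_n_nodes=22, ref_n_edges=55,
        truth_metric_n_random=10,
        master_seed=11,
    )
    fluency, scores, registry = simulate_cohort(config)
    return config, fluency, scores, registry
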