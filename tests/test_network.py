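"""Friendship network: degree constraints, homophily, small-world metrics."""
import networkx as nx
import numpy as np
import pytest

from upfsim import (
    NetworkConfig,
    PopulationConfig,
    build_network,
    generate_population,
    neighbor_mean_purchasing,
    network_metrics,
)

from conftest import manual_population, single_stratum_config, wrap_graph


def test_mean_degree_and_bounds():
    """Mean degree hits 5.47 and every node stays within [3, 50]."""
    pop = generate_population(PopulationConfig(), seed=1)
    for seed in range(5):
        net = build_network(pop, NetworkConfig(), seed)
        assert net.mean_degree == pytest.approx(5.47, abs=0.02)
        assert net.degrees.min() >= 3
        assert net.degrees.max() <= 50


def test_degree_bounds_tight_config():
    pop = generate_population(PopulationConfig(n_agents=60), seed=4)
    cfg = NetworkConfig(target_mean_degree=5.0, min_degree=4, max_degree=7,
                        homophily_weight=3.0)
    for seed in (0, 1, 2):
        net = build_network(pop, cfg, seed)
        assert net.degrees.min() >= 4
        assert net.degrees.max() <= 7


def _categorical_assortativity(edges: np.ndarray, labels: np.ndarray) -> float:
    """Mixing-matrix assortativity oracle, independent of networkx."""
    k = labels.max() + 1
    e = np.zeros((k, k))
    np.add.at(e, (labels[edges[:, 0]], labels[edges[:, 1]]), 1.0)
    np.add.at(e, (labels[edges[:, 1]], labels[edges[:, 0]]), 1.0)
    e /= e.sum()
    ab = e.sum(axis=0) @ e.sum(axis=1)
    return (np.trace(e) - ab) / (1.0 - ab)


def test_zero_homophily_assortativity_permutation_null():
    """With weight 0, education assortativity is indistinguishable from 0.

    The statistic is the mean assortativity over five builds; the null
    permutes the education labels 200 times over the same five graphs.
    """
    pop = generate_population(PopulationConfig(n_agents=500), seed=2)
    edu = pop.education.astype(int)
    edge_sets = [
        np.array(build_network(pop, NetworkConfig(homophily_weight=0.0), seed=s)
                 .edge_list())
        for s in range(5)
    ]

    def mean_assort(labels):
        return np.mean([_categorical_assortativity(e, labels) for e in edge_sets])

    observed = abs(mean_assort(edu))
    # sanity: the oracle agrees with networkx on one graph
    g = nx.Graph()
    g.add_nodes_from(range(len(pop)))
    g.add_edges_from(edge_sets[0])
    nx.set_node_attributes(g, {i: int(v) for i, v in enumerate(edu)}, "edu")
    assert _categorical_assortativity(edge_sets[0], edu) == pytest.approx(
        nx.attribute_assortativity_coefficient(g, "edu")
    )

    rng = np.random.default_rng(7)
    null = np.array([abs(mean_assort(rng.permutation(edu))) for _ in range(200)])
    assert observed <= np.percentile(null, 97.5)


def test_assortativity_monotone_in_homophily_weight():
    """Mean assortativity over seeds is non-decreasing in the weight."""
    pop = generate_population(PopulationConfig(n_agents=300), seed=5)
    weights = (0.0, 1.0, 5.0)
    means = {attr: [] for attr in ("age_group", "income_category", "education")}
    for w in weights:
        coeffs = {attr: [] for attr in means}
        for seed in range(20):
            net = build_network(pop, NetworkConfig(homophily_weight=w), seed)
            m = network_metrics(net, pop)
            for attr in means:
                coeffs[attr].append(m.assortativity_by[attr])
        for attr in means:
            means[attr].append(np.mean(coeffs[attr]))
    for attr, series in means.items():
        assert series[0] < series[1] < series[2], attr
    # strong homophily produces clearly positive education sorting
    assert means["education"][-1] > 0.2


def test_ring_lattice_matches_watts_strogatz_closed_form():
    """No rewiring, even target degree: exact k-regular ring metrics."""
    n, k = 40, 6
    pop = generate_population(PopulationConfig(n_agents=n), seed=6)
    cfg = NetworkConfig(target_mean_degree=float(k), rewire_probability=0.0,
                        homophily_weight=0.0)
    net = build_network(pop, cfg, seed=0)
    oracle = nx.watts_strogatz_graph(n, k, 0.0)
    metrics = network_metrics(net, pop)
    assert metrics.mean_degree == pytest.approx(k)
    assert metrics.clustering_coefficient == pytest.approx(
        nx.average_clustering(oracle)
    )
    assert metrics.clustering_coefficient == pytest.approx(3 * (k - 2) / (4 * (k - 1)))
    assert metrics.mean_path_length == pytest.approx(
        nx.average_shortest_path_length(oracle)
    )


def test_complete_graph_metrics():
    pop = generate_population(PopulationConfig(n_agents=5), seed=8)
    net = wrap_graph(nx.complete_graph(5))
    m = network_metrics(net, pop)
    assert m.clustering_coefficient == pytest.approx(1.0)
    assert m.mean_path_length == pytest.approx(1.0)
    assert m.mean_degree == pytest.approx(4.0)


def test_neighbor_mean_simple_cases():
    cfg = single_stratum_config(4)
    pop = manual_population([1000.0, 2000.0, 3000.0, 4000.0], cfg)
    g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 2)])
    net = wrap_graph(g)
    assert neighbor_mean_purchasing(net, pop, 0) == pytest.approx(3000.0)
    assert neighbor_mean_purchasing(net, pop, 3) == pytest.approx(1000.0)
    with pytest.raises(KeyError):
        neighbor_mean_purchasing(net, pop, 99)


def test_neighbor_mean_bruteforce_full_graph():
    """Every agent's value matches recomputation from the edge list."""
    pop = generate_population(PopulationConfig(n_agents=200), seed=9)
    net = build_network(pop, NetworkConfig(), seed=10)
    adj = {i: [] for i in range(len(pop))}
    for _, row in net.edge_list().iterrows():
        adj[row["source"]].append(row["target"])
        adj[row["target"]].append(row["source"])
    for i in range(len(pop)):
        expected = np.mean([pop.upf_kcal_week[j] for j in adj[i]])
        assert neighbor_mean_purchasing(net, pop, i) == pytest.approx(expected)


def test_generation_reproducible():
    pop = generate_population(PopulationConfig(n_agents=300), seed=11)
    e1 = build_network(pop, NetworkConfig(), seed=12).edge_list()
    e2 = build_network(pop, NetworkConfig(), seed=12).edge_list()
    e3 = build_network(pop, NetworkConfig(), seed=13).edge_list()
    assert e1.equals(e2)
    assert not e1.equals(e3)


def test_errors():
    tiny = generate_population(PopulationConfig(n_agents=3), seed=0)
    with pytest.raises(ValueError):
        build_network(tiny, NetworkConfig(), seed=0)
    with pytest.raises(ValueError):
        NetworkConfig(min_degree=10, target_mean_degree=5.0)
    with pytest.raises(ValueError):
        NetworkConfig(rewire_probability=1.5)
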