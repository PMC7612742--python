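"""Homophilous small-world friendship network between agents.

Ties represent close friendships between women in different households.
Construction is a degree-constrained variant of a Watts-Strogatz lattice:

1. agents are placed on a ring ordered by a noisy one-dimensional embedding
   of their (income, education, age) stratum, with the homophily weight
   setting the signal-to-noise ratio of the ordering (weight 0 gives a
   random ring, large weights sort agents into contiguous stratum blocks);
2. each agent is wired to her nearest ring neighbours (an even base degree
   below the target mean degree);
3. a fraction ``rewire_probability`` of lattice edges is rewired to
   endpoints sampled with probability proportional to
   ``exp(homophily_weight * similarity)``, creating long-range shortcuts;
4. extra edges are added the same way until the edge count matches the
   target mean degree exactly (5.47 at n = 1000 means 2735 edges);
5. a repair pass tops up any node below the minimum degree.

Similarity between two agents is the fraction of matching attributes among
age group, income category and education (0, 1/3, 2/3 or 1).  Degree bounds
(at least 3, at most 50 ties) hold for every node by construction.  The
network is static once built.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

from .population import (
    AgeGroup,
    Education,
    IncomeCategory,
    N_STRATA,
    Population,
    stratum_label,
)

__all__ = [
    "NetworkConfig",
    "SocialNetwork",
    "NetworkMetrics",
    "build_network",
    "network_metrics",
    "neighbor_mean_purchasing",
]

# pairwise similarity between strata: mean of three indicator matches
_SIM = np.empty((N_STRATA, N_STRATA))
for _s in range(N_STRATA):
    _a1, _i1, _e1 = stratum_label(_s)
    for _t in range(N_STRATA):
        _a2, _i2, _e2 = stratum_label(_t)
        _SIM[_s, _t] = ((_a1 == _a2) + (_i1 == _i2) + (_e1 == _e2)) / 3.0


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the friendship-network generator.

    ``homophily_weight`` is a calibrated, dimensionless weight on attribute
    similarity in both the ring ordering and the sampling of rewired/extra
    edge endpoints; 0 removes homophily entirely.  The default is the value
    selected by the calibration procedure (see :mod:`upfsim.calibration`).
    """

    target_mean_degree: float = 5.47
    min_degree: int = 3
    max_degree: int = 50
    homophily_weight: float = 6.0
    rewire_probability: float = 0.1

    def __post_init__(self):
        if not 0 < self.min_degree <= self.target_mean_degree <= self.max_degree:
            raise ValueError(
                "degree bounds must satisfy 0 < min <= target mean <= max"
            )
        if self.homophily_weight < 0:
            raise ValueError("homophily_weight must be non-negative")
        if not 0.0 <= self.rewire_probability <= 1.0:
            raise ValueError("rewire_probability must lie in [0, 1]")


class SocialNetwork:
    """Static undirected friendship graph over agent ids ``0..n-1``."""

    def __init__(self, graph: nx.Graph, config: NetworkConfig):
        self.graph = graph
        self.config = config
        self._csr: sp.csr_array | None = None
        self._degrees: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    @property
    def degrees(self) -> np.ndarray:
        if self._degrees is None:
            deg = np.zeros(self.n_nodes, dtype=float)
            for node, d in self.graph.degree():
                deg[node] = d
            self._degrees = deg
        return self._degrees

    def adjacency_csr(self) -> sp.csr_array:
        """Cached CSR adjacency with nodes ordered by agent id."""
        if self._csr is None:
            self._csr = sp.csr_array(
                nx.to_scipy_sparse_array(
                    self.graph, nodelist=range(self.n_nodes), dtype=float
                )
            )
        return self._csr

    def neighbors(self, agent_id: int):
        return list(self.graph.neighbors(agent_id))

    def edge_list(self) -> pd.DataFrame:
        edges = sorted(tuple(sorted(e)) for e in self.graph.edges())
        return pd.DataFrame(edges, columns=["source", "target"])

    def to_csv(self, path) -> None:
        self.edge_list().to_csv(path, index=False)


@dataclass(frozen=True)
class NetworkMetrics:
    mean_degree: float
    clustering_coefficient: float
    mean_path_length: float
    assortativity_by: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_degree": self.mean_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "mean_path_length": self.mean_path_length,
            "assortativity_by": dict(self.assortativity_by),
        }


class _HomophilySampler:
    """Samples edge endpoints with probability ∝ exp(w * similarity).

    Similarity depends only on the stratum pair, so sampling is two-stage:
    pick a stratum from the 12-cell categorical (weights = stratum size x
    exp(w * similarity)), then a uniform member, with rejection of
    ineligible partners.
    """

    def __init__(self, codes: np.ndarray, weight: float, max_degree: int, rng):
        self.codes = codes
        self.weight = weight
        self.max_degree = max_degree
        self.rng = rng
        self.members = [np.flatnonzero(codes == s) for s in range(N_STRATA)]
        counts = np.array([len(m) for m in self.members], dtype=float)
        probs = counts[None, :] * np.exp(weight * _SIM)
        probs /= probs.sum(axis=1, keepdims=True)
        self.probs = probs  # row: stratum of the anchor agent

    def sample(self, u: int, adj: list[set], deg: np.ndarray) -> int | None:
        su = self.codes[u]
        for _ in range(200):
            s = self.rng.choice(N_STRATA, p=self.probs[su])
            members = self.members[s]
            v = int(members[self.rng.integers(len(members))])
            if v != u and v not in adj[u] and deg[v] < self.max_degree:
                return v
        # dense fallback for pathological cases (tiny populations)
        candidates = np.array(
            [
                v
                for v in range(len(self.codes))
                if v != u and v not in adj[u] and deg[v] < self.max_degree
            ]
        )
        if len(candidates) == 0:
            return None
        w = np.exp(self.weight * _SIM[su, self.codes[candidates]])
        return int(self.rng.choice(candidates, p=w / w.sum()))


def build_network(
    population: Population, config: NetworkConfig, seed
) -> SocialNetwork:
    """Build the homophilous small-world friendship graph.

    Deterministic given ``seed`` and inputs; every node ends with degree in
    ``[min_degree, max_degree]`` and the mean degree equals
    ``round(n * target_mean_degree / 2) * 2 / n`` (5.47 exactly at n=1000).
    """
    n = len(population)
    if n < config.min_degree + 1:
        raise ValueError("population too small for the minimum degree")
    if config.target_mean_degree > n - 1:
        raise ValueError("target mean degree infeasible for this population size")
    rng = np.random.default_rng(seed)
    codes = population.stratum_codes.astype(int)
    w = config.homophily_weight

    # ring ordering by noisy stratum embedding; income is the outermost key
    embed = (
        population.income_cat.astype(int) * (len(Education) * len(AgeGroup))
        + population.education.astype(int) * len(AgeGroup)
        + population.age_group.astype(int)
    )
    key = w * embed + rng.standard_normal(n)
    order = np.argsort(key, kind="stable")

    adj: list[set] = [set() for _ in range(n)]
    deg = np.zeros(n, dtype=int)
    edges: list[tuple[int, int]] = []

    def add_edge(a: int, b: int) -> None:
        adj[a].add(b)
        adj[b].add(a)
        deg[a] += 1
        deg[b] += 1
        edges.append((a, b))

    def remove_edge(a: int, b: int) -> None:
        adj[a].discard(b)
        adj[b].discard(a)
        deg[a] -= 1
        deg[b] -= 1

    k_half = max(1, int(config.target_mean_degree // 2))
    k_half = min(k_half, (n - 1) // 2)
    for d in range(1, k_half + 1):
        for i in range(n):
            u, v = int(order[i]), int(order[(i + d) % n])
            if u != v and v not in adj[u]:
                add_edge(u, v)

    sampler = _HomophilySampler(codes, w, config.max_degree, rng)

    # rewire a fraction of lattice edges to homophily-sampled long-range ties
    lattice_edges = list(edges)
    rewire = rng.random(len(lattice_edges)) < config.rewire_probability
    for (u, v), flag in zip(lattice_edges, rewire):
        if not flag or deg[v] <= config.min_degree:
            continue
        new_v = sampler.sample(u, adj, deg)
        if new_v is None:
            continue
        remove_edge(u, v)
        edges.remove((u, v))
        add_edge(u, new_v)

    # top up to the exact target edge count
    target_edges = int(round(config.target_mean_degree * n / 2.0))
    eligible = np.arange(n)
    attempts = 0
    while len(edges) < target_edges and attempts < 50 * target_edges:
        attempts += 1
        open_nodes = eligible[deg[eligible] < config.max_degree]
        if len(open_nodes) < 2:
            break
        u = int(open_nodes[rng.integers(len(open_nodes))])
        v = sampler.sample(u, adj, deg)
        if v is not None:
            add_edge(u, v)

    # repair: guarantee the minimum degree
    for u in np.flatnonzero(deg < config.min_degree):
        while deg[u] < config.min_degree:
            v = sampler.sample(int(u), adj, deg)
            if v is None:
                raise ValueError("degree bounds infeasible: repair pass failed")
            add_edge(int(u), v)

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(edges)
    return SocialNetwork(graph, config)


def network_metrics(network: SocialNetwork, population: Population) -> NetworkMetrics:
    """Mean degree, clustering, mean path length and attribute assortativity.

    The mean shortest path length is computed on the largest connected
    component (rewiring can, rarely, disconnect the graph).  Assortativity
    is the categorical (discrete) assortativity coefficient for each of the
    three homophily attributes.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_nodes() != len(population):
        raise ValueError("network does not cover the population")

    csr = network.adjacency_csr()
    n_comp, labels = connected_components(csr, directed=False)
    largest = np.flatnonzero(labels == np.bincount(labels).argmax())
    sub = csr[largest][:, largest]
    dist = shortest_path(sub, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(len(largest), k=1)
    mean_path = float(dist[iu].mean()) if len(largest) > 1 else 0.0

    attrs = {
        "age_group": population.age_group,
        "income_category": population.income_cat,
        "education": population.education,
    }
    assort = {}
    for name, values in attrs.items():
        nx.set_node_attributes(g, {i: int(v) for i, v in enumerate(values)}, name)
        try:
            coeff = float(nx.attribute_assortativity_coefficient(g, name))
        except ZeroDivisionError:  # single-category attribute
            coeff = float("nan")
        assort[name] = coeff

    return NetworkMetrics(
        mean_degree=network.mean_degree,
        clustering_coefficient=float(nx.average_clustering(g)),
        mean_path_length=mean_path,
        assortativity_by=assort,
    )


def neighbor_mean_purchasing(
    network: SocialNetwork,
    population: Population,
    agent_id: int,
    values: np.ndarray | None = None,
) -> float:
    """Arithmetic mean purchasing among an agent's direct neighbours.

    ``values`` allows passing a start-of-step snapshot; by default the
    population's current purchasing values are used.
    """
    if agent_id not in network.graph:
        raise KeyError(f"unknown agent id {agent_id}")
    if values is None:
        values = population.upf_kcal_week
    neigh = network.neighbors(agent_id)
    if not neigh:
        raise ValueError(f"agent {agent_id} has no neighbours")
    return float(np.mean([values[v] for v in neigh]))
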