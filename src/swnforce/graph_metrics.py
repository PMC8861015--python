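"""Graph-theoretic characterisation of network topologies.

Small-Worldness Index (SWI), characteristic path length, clustering, and
Latora-Marchiori global/local efficiency, with multi-trial sweeps over the
Watts-Strogatz rewiring probability.

All metrics operate on the binarized, undirected skeleton of a network
(edge presence only), matching the unweighted Watts-Strogatz setting in
which the SWI baselines are defined.  Path lengths are hop counts from
breadth-first search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .topology import GraphSpec, WeightedNetwork, generate_watts_strogatz

__all__ = [
    "GraphMetricsReport",
    "skeleton",
    "clustering_coefficient",
    "characteristic_path_length",
    "swi",
    "global_efficiency",
    "local_efficiency",
    "sweep_beta",
]


@dataclass(frozen=True)
class GraphMetricsReport:
    """Trial-averaged metrics of a Watts-Strogatz ensemble at one beta."""

    beta: float
    clustering: float
    char_path_length: float
    swi: float
    global_efficiency: float
    local_efficiency: float
    n_trials: int


def skeleton(network) -> nx.Graph:
    """Binarized undirected graph underlying a network.

    Accepts a :class:`~swnforce.topology.WeightedNetwork` or any networkx
    graph (returned undirected and unweighted).
    """
    if isinstance(network, WeightedNetwork):
        g = nx.from_numpy_array((network.weights != 0).astype(np.int8))
        g.remove_edges_from(nx.selfloop_edges(g))
        return g
    return nx.Graph(network)


def _hop_distances(graph: nx.Graph) -> np.ndarray:
    """All-pairs BFS hop-count matrix (np.inf for unreachable pairs)."""
    adj = csr_array(nx.to_scipy_sparse_array(graph, dtype=np.int8))
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def clustering_coefficient(graph: nx.Graph) -> float:
    """Node-averaged local clustering (Watts-Strogatz convention)."""
    return nx.average_clustering(graph)


def characteristic_path_length(graph: nx.Graph, largest_component: bool = True) -> float:
    """Mean BFS hop count over connected ordered pairs.

    On a disconnected graph the mean over all pairs is undefined; with
    ``largest_component=True`` (default) the metric is computed on the
    largest connected component with a warning, otherwise a ValueError is
    raised.
    """
    if not nx.is_connected(graph):
        if not largest_component:
            raise ValueError("graph is disconnected; path length undefined")
        warnings.warn(
            "graph disconnected: characteristic path length computed on the "
            "largest connected component",
            stacklevel=2,
        )
        graph = graph.subgraph(max(nx.connected_components(graph), key=len))
    dist = _hop_distances(graph)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    return float(dist[off].mean())


def swi(graph: nx.Graph, mean_degree: float | None = None) -> float:
    """Small-Worldness Index against analytic random-graph baselines.

    sigma = (gamma_G / gamma_rand) / (lambda_G / lambda_rand) with
    gamma_rand = K/N and lambda_rand = ln(N)/ln(K), the expected
    clustering and mean path length of an Erdos-Renyi graph with the same
    mean degree K.  sigma >> 1 indicates small-world structure.
    """
    n = graph.number_of_nodes()
    k = mean_degree if mean_degree is not None else 2 * graph.number_of_edges() / n
    if k <= 1:
        raise ValueError("SWI baselines require mean degree > 1")
    gamma = clustering_coefficient(graph)
    lam = characteristic_path_length(graph)
    gamma_rand = k / n
    lam_rand = np.log(n) / np.log(k)
    return (gamma / gamma_rand) / (lam / lam_rand)


def global_efficiency(graph: nx.Graph) -> float:
    """Mean inverse hop count over ordered node pairs.

    Unreachable pairs contribute zero efficiency, so disconnection is
    handled without special-casing; a complete graph scores exactly 1.
    """
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    dist = _hop_distances(graph)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0  # unreachable pairs and the diagonal
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(graph: nx.Graph) -> float:
    """Mean over nodes of the global efficiency of each open neighbourhood.

    A node with fewer than two neighbours has no pairs to route between
    and contributes zero (a star graph therefore scores 0).
    """
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    total = 0.0
    for node in graph:
        nbrs = list(graph.neighbors(node))
        if len(nbrs) < 2:
            continue
        total += global_efficiency(graph.subgraph(nbrs))
    return total / n


def sweep_beta(
    n_nodes: int,
    mean_degree: int,
    betas,
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial-averaged SWI and efficiencies across rewiring probabilities.

    For each beta, ``n_trials`` freshly seeded Watts-Strogatz graphs are
    generated and the arithmetic means of sigma, E_G and E_L recorded.

    Returns a DataFrame with columns ``beta, swi_mean, ge_mean, le_mean,
    cc_mean, cpl_mean, trials``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for beta in betas:
        acc = np.zeros(5)
        for _ in range(n_trials):
            spec = GraphSpec(
                n_nodes, mean_degree, beta, seed=int(rng.integers(0, 2**31 - 1))
            )
            g = generate_watts_strogatz(spec)
            acc += [
                swi(g, mean_degree=mean_degree),
                global_efficiency(g),
                local_efficiency(g),
                clustering_coefficient(g),
                characteristic_path_length(g),
            ]
        acc /= n_trials
        rows.append(
            {
                "beta": beta,
                "swi_mean": acc[0],
                "ge_mean": acc[1],
                "le_mean": acc[2],
                "cc_mean": acc[3],
                "cpl_mean": acc[4],
                "trials": n_trials,
            }
        )
    return pd.DataFrame(rows)


def report(graph: nx.Graph, beta: float = float("nan"), n_trials: int = 1) -> GraphMetricsReport:
    """Bundle all metrics of a single graph into a report."""
    return GraphMetricsReport(
        beta=beta,
        clustering=clustering_coefficient(graph),
        char_path_length=characteristic_path_length(graph),
        swi=swi(graph),
        global_efficiency=global_efficiency(graph),
        local_efficiency=local_efficiency(graph),
        n_trials=n_trials,
    )
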