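"""Topology metrics: clustering, path length and the small-world coefficient.

The small-world coefficient follows Humphries' ratio-of-ratios,

    SW = gamma / phi,   gamma = cc_graph / cc_rand,   phi = cpl_graph / cpl_rand,

where the random references are uniform Erdos–Renyi G(n, m) graphs with the
same number of vertices and edges as the measured graph, and cc_rand / cpl_rand
are measured empirically on sampled replicates (not analytic approximations).
SW ≈ 1 for random graphs and SW > 1 for small-world graphs.

Connectivity policy (the generator routinely yields isolated nodes):
cpl averages shortest-path hop counts over *connected* ordered-distinct pairs
only; a graph whose largest component has fewer than 2 nodes, or with zero
clustering, reports SW = 0.  cc_rand = 0 across every replicate leaves gamma
undefined and SW is reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netgen import Network

__all__ = [
    "TopologyMetrics",
    "clustering_coefficient",
    "characteristic_path_length",
    "er_graph",
    "small_world",
]

DEFAULT_N_REPLICATES = 20


@dataclass
class TopologyMetrics:
    cc_graph: float
    cpl_graph: float
    cc_rand: float
    cpl_rand: float
    gamma: float
    phi: float
    sw: float
    n_rand_replicates: int


def _as_graph(net: Network | nx.Graph) -> nx.Graph:
    return net.to_networkx() if isinstance(net, Network) else net


def clustering_coefficient(net: Network | nx.Graph) -> float:
    """Mean Watts–Strogatz local clustering; degree-<2 nodes contribute 0."""
    g = _as_graph(net)
    if g.number_of_nodes() < 3:
        raise ValueError("clustering coefficient requires n >= 3")
    return float(nx.average_clustering(g))


def characteristic_path_length(net: Network | nx.Graph) -> float:
    """Mean shortest-path hop count over connected ordered-distinct pairs.

    Disconnected pairs are excluded.  Raises if the graph has no edges (no
    connected pair exists, cpl is undefined).
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("characteristic path length requires n >= 2")
    if g.number_of_edges() == 0:
        raise ValueError("cpl undefined on an edgeless graph")
    nodes = sorted(g.nodes())
    idx = {u: i for i, u in enumerate(nodes)}
    rows, cols = [], []
    for u, v in g.edges():
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    finite = np.isfinite(dist) & (dist > 0)
    return float(dist[finite].mean())


def er_graph(n: int, m: int, seed: int | np.random.Generator) -> nx.Graph:
    """Uniform G(n, m): exactly m distinct edges, no self-loops."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m must be in [0, {max_m}], got {m}")
    rng = np.random.default_rng(seed)
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    return g


def small_world(
    net: Network | nx.Graph,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | np.random.Generator = 0,
) -> TopologyMetrics:
    """Measure SW = (cc/cc_rand) / (cpl/cpl_rand) against G(n, m) replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    g = _as_graph(net)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m < 1:
        return TopologyMetrics(0.0, np.nan, np.nan, np.nan, np.nan, np.nan, 0.0, n_replicates)
    cc_g = clustering_coefficient(g)
    cpl_g = characteristic_path_length(g)
    rng = np.random.default_rng(seed)
    cc_r = np.empty(n_replicates)
    cpl_r = np.empty(n_replicates)
    for r in range(n_replicates):
        ref = er_graph(n, m, rng)
        cc_r[r] = nx.average_clustering(ref)
        cpl_r[r] = characteristic_path_length(ref)
    cc_rand = float(cc_r.mean())
    cpl_rand = float(cpl_r.mean())
    if cc_g == 0.0:
        sw = gamma = 0.0
        phi = cpl_g / cpl_rand
    elif cc_rand == 0.0:
        gamma = np.nan
        phi = cpl_g / cpl_rand
        sw = np.nan  # undefined: reference graphs carry no triangles
    else:
        gamma = cc_g / cc_rand
        phi = cpl_g / cpl_rand
        sw = gamma / phi
    return TopologyMetrics(
        cc_graph=cc_g,
        cpl_graph=cpl_g,
        cc_rand=cc_rand,
        cpl_rand=cpl_rand,
        gamma=float(gamma),
        phi=float(phi),
        sw=float(sw),
        n_rand_replicates=n_replicates,
    )
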