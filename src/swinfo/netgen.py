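"""Generation of 2D spatial neuronal networks with tunable small-world-ness.

Point clouds are sampled from a mixture of isotropic Gaussians placed in a
square domain (default 10x10) and wired with a mixed rule combining

* a *distance rule* (a Waxman-type kernel): nodes i, j are linked when
  ``p1(i,j) = alpha * exp(-beta * d_ij / l) > P_w`` where ``l`` is the maximal
  inter-nodal distance — this creates short-range, intra-cluster links;
* a *density rule* (a density-peak score in the spirit of Rodriguez & Laio's
  cluster-center finder): each node k gets
  ``p2(k) = exp(-(Gamma_max / Gamma_k - 1))`` with ``Gamma_k = rho_k * dmin_k``,
  ``rho_k`` the number of points within a cutoff ``delta_co`` of k and
  ``dmin_k`` the distance to the nearest point of strictly higher density;
  nodes i, j are linked when both ``p2 > P_d`` — this creates long-range links
  between cluster centers.

An edge exists when either test passes.  Given the cloud and the parameters the
rule is fully deterministic; all randomness lives in the point sampling and in
the ensemble-level parameter draws.  Sweeping ``P_w``, ``P_d``, ``beta`` and
``delta_co`` over their stated ranges yields ensembles whose measured
small-world coefficient spans roughly 0–14.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GaussianComponent",
    "PointCloud",
    "WiringParams",
    "Network",
    "sample_points",
    "distance_probability",
    "density_scores",
    "wire",
    "generate_ensemble",
]

DOMAIN_SIDE = 10.0
N_COMPONENTS = 6
SIGMA_CENTER = 0.2
SIGMA_JITTER = 0.1
DELTA_CO_MAX = 0.4


@dataclass(frozen=True)
class GaussianComponent:
    """One isotropic Gaussian of the spatial mixture."""

    x_o: float
    y_o: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class PointCloud:
    """Sampled node positions, with the mixture component of each point."""

    coords: np.ndarray  # (n, 2) float
    domain_side: float = DOMAIN_SIDE
    component_labels: np.ndarray | None = None  # (n,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if self.component_labels is not None:
            self.component_labels = np.asarray(self.component_labels, dtype=int)
            if len(self.component_labels) != len(self.coords):
                raise ValueError("one component label per point required")

    @property
    def n_points(self) -> int:
        return len(self.coords)


@dataclass
class WiringParams:
    """Parameters of the mixed wiring rule.

    ``l`` (the maximal inter-nodal distance) is computed from the cloud at
    wiring time and stored back for provenance, never user-set.
    """

    alpha: float = 1.0
    beta: float = 0.2
    P_w: float = 0.95
    P_d: float = 0.95
    delta_co: float = 0.2
    l: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.P_w < 0 or self.P_d < 0:
            raise ValueError("thresholds must be >= 0")
        if self.delta_co < 0:
            raise ValueError("delta_co must be >= 0")


@dataclass
class Network:
    """Spatial undirected network: node coordinates + boolean adjacency."""

    coords: np.ndarray  # (n, 2)
    adjacency: np.ndarray  # (n, n) bool, symmetric, zero diagonal
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.coords)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be (n, n)")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of 0-based index pairs, i < j, lexicographic."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju]
        return np.column_stack([iu[mask], ju[mask]])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_list()))
        for i, (x, y) in enumerate(self.coords):
            g.nodes[i]["x"] = float(x)
            g.nodes[i]["y"] = float(y)
        return g

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def sample_points(
    components: Sequence[GaussianComponent],
    n_points: int,
    seed: int | np.random.Generator,
) -> PointCloud:
    """Sample ``n_points`` from the Gaussian mixture, near-equally per component.

    Points are divided as evenly as possible across components; the first
    ``n_points mod k`` components receive one extra point.  Points falling
    outside the nominal domain are kept.
    """
    if len(components) == 0:
        raise ValueError("at least one mixture component is required")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(components)
    counts = np.full(k, n_points // k, dtype=int)
    counts[: n_points % k] += 1
    coords = []
    labels = []
    for idx, (comp, c) in enumerate(zip(components, counts)):
        center = np.array([comp.x_o, comp.y_o])
        coords.append(rng.normal(loc=center, scale=comp.sigma, size=(c, 2)))
        labels.append(np.full(c, idx, dtype=int))
    return PointCloud(
        coords=np.concatenate(coords),
        component_labels=np.concatenate(labels),
    )


def distance_probability(
    d_ij: float | np.ndarray, params: WiringParams
) -> float | np.ndarray:
    """Waxman-type distance score ``p1 = alpha * exp(-beta * d / l)``."""
    if params.l is None or params.l <= 0:
        raise ValueError(
            "maximal inter-nodal distance l is not set or zero (degenerate cloud)"
        )
    d = np.asarray(d_ij, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = params.alpha * np.exp(-params.beta * d / params.l)
    return float(out) if np.isscalar(d_ij) else out


def density_scores(cloud: PointCloud, delta_co: float) -> np.ndarray:
    """Density-peak score ``p2(k) = exp(-(Gamma_max/Gamma_k - 1))`` per node.

    rho_k counts *other* points within ``delta_co`` (d <= delta_co, d > 0).
    dmin_k is the minimum distance to a point of higher density, where "higher"
    means strictly greater rho, with density ties broken by node index (a
    tied point of lower index counts as denser).  The globally densest point
    takes dmin equal to the maximum pairwise distance (density-peak
    convention).  Nodes with Gamma = 0 (rho = 0) score 0; if every Gamma is 0
    the cutoff carries no density contrast and an error is raised.
    """
    n = cloud.n_points
    if n < 2:
        raise ValueError("need at least 2 points")
    d = squareform(pdist(cloud.coords))
    rho = ((d <= delta_co) & (d > 0)).sum(axis=1)
    d_max = d.max()
    # rank[k] strictly ordered: higher rho first, then lower index
    order = np.lexsort((np.arange(n), -rho))  # order[0] is the densest
    dmin = np.empty(n, dtype=float)
    dmin[order[0]] = d_max
    for pos in range(1, n):
        k = order[pos]
        denser = order[:pos]
        dmin[k] = d[k, denser].min()
    gamma = rho * dmin
    gamma_max = gamma.max()
    if gamma_max <= 0:
        raise ValueError(
            "all Gamma are zero: delta_co too small for any density contrast"
        )
    scores = np.zeros(n, dtype=float)
    pos_mask = gamma > 0
    scores[pos_mask] = np.exp(-(gamma_max / gamma[pos_mask] - 1.0))
    return scores


def wire(cloud: PointCloud, params: WiringParams) -> Network:
    """Apply the mixed wiring rule; deterministic given cloud and params.

    Edge (i, j) exists iff ``p1(i,j) > P_w`` or ``p2(i) > P_d and p2(j) > P_d``.
    """
    if cloud.n_points < 2:
        raise ValueError("need at least 2 points to wire")
    d = squareform(pdist(cloud.coords))
    l = float(d.max())
    if l <= 0:
        raise ValueError("all points coincide: degenerate cloud, l = 0")
    params.l = l
    p1 = params.alpha * np.exp(-params.beta * d / l)
    adj = p1 > params.P_w
    if params.delta_co > 0:
        try:
            p2 = density_scores(cloud, params.delta_co)
        except ValueError:
            p2 = np.zeros(cloud.n_points)
        hub = p2 > params.P_d
        adj |= hub[:, None] & hub[None, :]
    np.fill_diagonal(adj, False)
    return Network(
        coords=cloud.coords.copy(),
        adjacency=adj,
        provenance={
            "alpha": params.alpha,
            "beta": params.beta,
            "P_w": params.P_w,
            "P_d": params.P_d,
            "delta_co": params.delta_co,
            "l": l,
        },
    )


def generate_ensemble(
    n_configs: int,
    n_points: int = 500,
    seed: int | np.random.Generator = 0,
    n_components: int = N_COMPONENTS,
    beta_range: tuple[float, float] = (0.2, 0.8),
    P_w_range: tuple[float, float] = (0.90, 1.0),
    P_d_range: tuple[float, float] = (0.90, 1.0),
    delta_co_max: float = DELTA_CO_MAX,
    domain_side: float = DOMAIN_SIDE,
    dense_fraction: float = 0.0,
) -> list[Network]:
    """Draw ``n_configs`` networks with wiring parameters from the stated ranges.

    Per configuration: component centers uniform in the square domain, per-
    component sigma uniform in 0.2 ± 0.1, alpha fixed at 1, beta ~ U(0.2, 0.8),
    P_w ~ U(0.90, 1.0), P_d ~ U(0.90, 1.0), delta_co ~ U(0, 0.4] (a zero cutoff
    makes the density rule degenerate, so draws are clipped away from 0).
    Provenance (all draws + per-config seed) is stored on each network.

    ``dense_fraction`` draws that share of configurations from the extreme
    dense corner of the same intervals (the lowest 5% of the beta and P_w
    ranges, i.e. the largest distance thresholds): these are the most
    random-like graphs (SW near 1) and under purely uniform draws that end of
    the SW axis is essentially never populated.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    for lo, hi in (beta_range, P_w_range, P_d_range):
        if not lo <= hi:
            raise ValueError("invalid range bounds")
    root = np.random.default_rng(seed)
    n_dense = int(round(dense_fraction * n_configs))
    nets: list[Network] = []
    for cfg in range(n_configs):
        rng = np.random.default_rng(root.integers(2**31))
        centers = rng.uniform(0, domain_side, size=(n_components, 2))
        sigmas = rng.uniform(SIGMA_CENTER - SIGMA_JITTER, SIGMA_CENTER + SIGMA_JITTER, n_components)
        comps = [
            GaussianComponent(float(x), float(y), float(s))
            for (x, y), s in zip(centers, sigmas)
        ]
        cloud = sample_points(comps, n_points, rng)
        if cfg < n_dense:
            b_rng = (beta_range[0], beta_range[0] + 0.05 * (beta_range[1] - beta_range[0]))
            w_rng = (P_w_range[0], P_w_range[0] + 0.05 * (P_w_range[1] - P_w_range[0]))
        else:
            b_rng, w_rng = beta_range, P_w_range
        params = WiringParams(
            alpha=1.0,
            beta=float(rng.uniform(*b_rng)),
            P_w=float(rng.uniform(*w_rng)),
            P_d=float(rng.uniform(*P_d_range)),
            delta_co=float(max(rng.uniform(0.0, delta_co_max), 1e-9)),
        )
        net = wire(cloud, params)
        net.provenance.update(
            config_index=cfg,
            sigmas=[float(s) for s in sigmas],
            centers=centers.tolist(),
            n_points=n_points,
        )
        nets.append(net)
    return nets
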