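"""Topology metrics: weighted modularity, communities, degree outliers.

Rewired networks are classified along a modular-centralized axis.
Modularity Q (Newman's weighted form) is high for networks made of
densely intra-connected clusters and low for centralized ones, where a
few hubs carry most connections.  Because near-random networks also have
low Q, the proportion of degree *outliers* — nodes whose degree falls
outside ``<k> +/- 3 sqrt(<k>)``, the 3-sigma band of the Poisson degree
distribution of a comparable random graph — is used as a complementary
signature of centralization.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .graph import WeightedGraph

__all__ = [
    "PartitionResult",
    "OutlierSpec",
    "modularity",
    "detect_communities",
    "outlier_proportion",
    "classify_topology",
    "degree_histogram",
    "strength_histogram",
    "Q_CENTRALIZED_MAX",
    "Q_MODULAR_MIN",
]

#: Q below this is classified centralized; between the two is the gray zone.
Q_CENTRALIZED_MAX = 0.45
#: Q above this is classified modular.
Q_MODULAR_MIN = 0.50


@dataclass
class PartitionResult:
    """A community assignment and its modularity."""

    assignment: np.ndarray
    q: float


def modularity(G: WeightedGraph, assignment: np.ndarray) -> float:
    """Weighted Newman modularity of a partition.

    ``Q = 1/(2m) * sum_ij [A_ij - s_i s_j / (2m)] delta(c_i, c_j)`` with
    ``m`` the total edge weight.  Evaluated per community:
    ``Q = sum_c [ W_c / (2m) - (S_c / (2m))^2 ]`` where ``W_c`` is the
    (both-orders) weight inside community c and ``S_c`` its strength sum.
    """
    assignment = np.asarray(assignment)
    if assignment.shape != (G.n,):
        raise ValueError(
            f"assignment has length {assignment.shape}, expected ({G.n},)"
        )
    A = G.adjacency
    two_m = A.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    s = A.sum(axis=1)
    _, labels = np.unique(assignment, return_inverse=True)
    k = labels.max() + 1
    C = np.zeros((G.n, k))
    C[np.arange(G.n), labels] = 1.0
    W_c = np.einsum("ic,ij,jc->c", C, A, C)
    S_c = s @ C
    return float(np.sum(W_c / two_m - (S_c / two_m) ** 2))


def detect_communities(G: WeightedGraph, seed: int | None = None) -> PartitionResult:
    """Multilevel (Louvain) modularity maximization.

    Delegates to igraph's ``community_multilevel`` on the weighted graph;
    the returned Q is re-evaluated with :func:`modularity` so it is exact
    for the assignment.  igraph draws node orderings from Python's global
    ``random`` module, so the seed is applied to (and then restored from)
    that generator to keep runs reproducible.
    """
    u, v, w = G.edges()
    g = ig.Graph(n=G.n, edges=list(zip(u.tolist(), v.tolist())))
    state = _pyrandom.getstate()
    try:
        if seed is not None:
            _pyrandom.seed(seed)
        clustering = g.community_multilevel(weights=w.tolist())
    finally:
        _pyrandom.setstate(state)
    assignment = np.asarray(clustering.membership)
    return PartitionResult(assignment=assignment, q=modularity(G, assignment))


@dataclass(frozen=True)
class OutlierSpec:
    """Poisson-baseline band for degree outliers.

    For a random graph with mean degree ``<k>`` the degree distribution
    is approximately Poisson with dispersion ``sqrt(<k>)``; degrees
    strictly outside ``<k> +/- 3 sqrt(<k>)`` are counted as outliers.
    """

    k_mean: float

    def __post_init__(self) -> None:
        if not self.k_mean > 0:
            raise ValueError(f"mean degree must be positive, got {self.k_mean}")

    @property
    def sigma_k(self) -> float:
        return math.sqrt(self.k_mean)

    @property
    def lower(self) -> float:
        return self.k_mean - 3.0 * self.sigma_k

    @property
    def upper(self) -> float:
        return self.k_mean + 3.0 * self.sigma_k

    @classmethod
    def from_graph(cls, G: WeightedGraph) -> "OutlierSpec":
        return cls(k_mean=2.0 * G.edge_count / G.n)


def outlier_proportion(G: WeightedGraph, spec: OutlierSpec | None = None) -> float:
    """Fraction of nodes with degree strictly outside the outlier band.

    With ``spec=None`` the band is centred on the graph's own mean degree
    (2m/n), which is conserved along a rewiring trajectory.
    """
    if spec is None:
        spec = OutlierSpec.from_graph(G)
    d = G.degrees
    return float(np.mean((d < spec.lower) | (d > spec.upper)))


def classify_topology(
    q: float, t_low: float = Q_CENTRALIZED_MAX, t_high: float = Q_MODULAR_MIN
) -> str:
    """Classify a modularity value as centralized / intermediate / modular."""
    if not t_low <= t_high:
        raise ValueError("thresholds must satisfy t_low <= t_high")
    if q < t_low:
        return "centralized"
    if q > t_high:
        return "modular"
    return "intermediate"


def degree_histogram(graphs: list[WeightedGraph]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled degree distribution over a list of graphs.

    Returns ``(degrees, proportions)`` with proportions summing to 1;
    replicate graphs contribute in proportion to their node counts.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    pooled = np.concatenate([G.degrees for G in graphs])
    values, counts = np.unique(pooled, return_counts=True)
    return values, counts / counts.sum()


def strength_histogram(
    graphs: list[WeightedGraph], bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled, binned strength distribution; returns (bin_centers, proportions)."""
    if not graphs:
        raise ValueError("need at least one graph")
    pooled = np.concatenate([G.strengths for G in graphs])
    counts, edges = np.histogram(pooled, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / counts.sum()
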