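"""Initial network generation: connected Erdos-Renyi topology + weights.

The simulations start from a random connected graph whose edge count
``m = round(2 ln(n) (n - 1))`` is dense enough that a uniform G(n, m)
draw is connected with overwhelming probability (for n = 100 this gives
m = 912, mean degree 18.24).  Edge weights are drawn either from a
normal distribution (mu = 1, sigma = 0.25; truncated to positive values)
or a lognormal one (mu = 0, sigma = 1), then rescaled so the weights sum
to the number of edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .graph import WeightedGraph

__all__ = [
    "WeightSpec",
    "NORMAL_WEIGHTS",
    "LOGNORMAL_WEIGHTS",
    "weight_spec",
    "edge_count",
    "random_topology",
    "sample_weights",
    "generate_initial_network",
]

_FAMILIES = ("normal", "lognormal")


@dataclass(frozen=True)
class WeightSpec:
    """Edge-weight distribution: family plus location/scale parameters.

    For ``family="normal"`` the weights are N(mu, sigma^2) truncated to
    positive values; for ``family="lognormal"`` they are LogN(mu, sigma^2)
    (mu and sigma on the log scale).
    """

    family: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown weight family {self.family!r}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


#: Default normal-network weights.
NORMAL_WEIGHTS = WeightSpec("normal", mu=1.0, sigma=0.25)
#: Default lognormal-network weights.
LOGNORMAL_WEIGHTS = WeightSpec("lognormal", mu=0.0, sigma=1.0)


def weight_spec(family: str) -> WeightSpec:
    """Default :class:`WeightSpec` for a family name."""
    if family == "normal":
        return NORMAL_WEIGHTS
    if family == "lognormal":
        return LOGNORMAL_WEIGHTS
    raise ValueError(f"unknown weight family {family!r}")


def edge_count(n: int) -> int:
    """Edge count ``m = round(2 ln(n) (n - 1))`` for an n-node network.

    This density (twice the ``ln(n)/n`` connectivity threshold of
    Erdos-Renyi graphs) makes a uniform random graph connected with
    overwhelming probability.  At n = 100 it gives m = 912 and mean
    degree 2m/n = 18.24.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    m = round(2.0 * math.log(n) * (n - 1))
    return int(min(m, n * (n - 1) // 2))


def _is_connected(A: np.ndarray) -> bool:
    ncomp, _ = connected_components(csr_matrix(A), directed=False)
    return ncomp == 1


def random_topology(n: int, m: int, rng: np.random.Generator | int) -> WeightedGraph:
    """Uniform connected G(n, m) graph with placeholder unit weights.

    Draws ``m`` distinct unordered node pairs uniformly at random and
    rejects (redraws) the sample until the graph is connected.  At the
    default density rejections are vanishingly rare.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    max_m = n * (n - 1) // 2
    if not 0 < m <= max_m:
        raise ValueError(f"m={m} outside (0, {max_m}] for n={n}")
    iu, iv = np.triu_indices(n, k=1)
    while True:
        chosen = rng.choice(max_m, size=m, replace=False)
        A = np.zeros((n, n))
        A[iu[chosen], iv[chosen]] = 1.0
        A[iv[chosen], iu[chosen]] = 1.0
        if _is_connected(A):
            return WeightedGraph(A, validate=False)


def sample_weights(
    spec: WeightSpec, m: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``m`` positive weights and rescale them to sum exactly to ``m``.

    Normal draws that come out nonpositive are redrawn (at the default
    mu = 1, sigma = 0.25 this happens with probability ~3e-5, so the
    truncation is statistically negligible).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if m < 1:
        raise ValueError(f"need m >= 1, got {m}")
    if spec.family == "normal":
        w = rng.normal(spec.mu, spec.sigma, size=m)
        bad = w <= 0
        while np.any(bad):
            w[bad] = rng.normal(spec.mu, spec.sigma, size=int(bad.sum()))
            bad = w <= 0
    else:
        w = rng.lognormal(spec.mu, spec.sigma, size=m)
    return w * (m / w.sum())


def generate_initial_network(
    n: int, spec: WeightSpec, rng: np.random.Generator | int
) -> WeightedGraph:
    """Connected random network with ``edge_count(n)`` weighted edges.

    Composes :func:`random_topology` with :func:`sample_weights`; the
    total weight of the result equals its edge count by construction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = edge_count(n)
    G = random_topology(n, m, rng)
    u, v, _ = G.edges()
    w = sample_weights(spec, m, rng)
    A = G.adjacency
    A[u, v] = w
    A[v, u] = w
    return G
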