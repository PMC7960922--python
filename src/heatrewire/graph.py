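"""Weighted undirected graphs, the normalized Laplacian, and heat kernels.

The diffusion model lives here: a network is an ``n x n`` symmetric
nonnegative adjacency matrix with zero diagonal, and "activity" on it is
heat flow generated by the normalized graph Laplacian
``L_norm = D^{-1/2} (D - A) D^{-1/2}``.  The heat kernel ``h(tau) =
expm(-tau * L_norm)`` gives the amount of heat exchanged between every
pair of nodes after diffusion time ``tau``; it is the quantity the
adaptive rewiring rule ranks candidate edges by.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedGraph",
    "HeatKernel",
    "normalized_laplacian",
    "heat_kernel",
    "heat_kernel_row",
    "SYMMETRY_TOL",
]

#: Absolute tolerance used when checking that an adjacency matrix is symmetric.
SYMMETRY_TOL = 1e-10


def _validate_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency contains non-finite entries")
    if np.any(A < 0):
        raise ValueError("adjacency contains negative weights")
    if not np.allclose(A, A.T, atol=SYMMETRY_TOL, rtol=0):
        raise ValueError("adjacency is not symmetric")
    if np.any(np.abs(np.diagonal(A)) > 0):
        raise ValueError("adjacency has nonzero diagonal (self-loops)")
    return A


@dataclass
class WeightedGraph:
    """A weighted undirected graph stored as a dense adjacency matrix.

    Parameters
    ----------
    adjacency
        ``n x n`` symmetric matrix of nonnegative connection weights with
        zero diagonal.  A zero entry means "no edge".

    Notes
    -----
    Node *strength* is the sum of a node's incident weights; *degree* is
    the count of its nonzero incident edges.  Both are recomputed from the
    matrix on access, so mutating ``adjacency`` in place is safe.
    """

    adjacency: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.validate:
            self.adjacency = _validate_adjacency(self.adjacency)
        else:
            self.adjacency = np.asarray(self.adjacency, dtype=float)

    # -- basic quantities -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return self.adjacency.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Per-node strength ``s_i = sum_j A_ij``."""
        return self.adjacency.sum(axis=1)

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree (count of incident nonzero-weight edges)."""
        return np.count_nonzero(self.adjacency, axis=1)

    @property
    def edge_count(self) -> int:
        """Number of undirected edges ``m``."""
        return int(np.count_nonzero(self.adjacency) // 2)

    @property
    def total_weight(self) -> float:
        """Sum of all edge weights (each undirected edge counted once)."""
        return float(self.adjacency.sum() / 2.0)

    # -- convenience ------------------------------------------------------

    def copy(self) -> "WeightedGraph":
        return WeightedGraph(self.adjacency.copy(), validate=False)

    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return arrays ``(u, v, w)`` of the undirected edges with u < v."""
        iu, iv = np.nonzero(np.triu(self.adjacency))
        return iu, iv, self.adjacency[iu, iv]

    @classmethod
    def from_edges(
        cls, n: int, u: np.ndarray, v: np.ndarray, w: np.ndarray
    ) -> "WeightedGraph":
        A = np.zeros((n, n))
        A[u, v] = w
        A[v, u] = w
        return cls(A)


@dataclass
class HeatKernel:
    """Heat kernel ``h(tau) = expm(-tau * L_norm)`` for a graph.

    ``matrix[i, j]`` is the amount of heat transferred between nodes *i*
    and *j* after diffusion time ``tau``; the matrix is symmetric with
    eigenvalues in ``(0, 1]`` for ``tau > 0`` and equals the identity at
    ``tau = 0``.
    """

    matrix: np.ndarray
    tau: float

    def __getitem__(self, idx):
        return self.matrix[idx]


def _inv_sqrt_strengths(s: np.ndarray) -> np.ndarray:
    # isolated nodes (s_i = 0) get 0, i.e. they exchange no heat
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 1.0 / np.sqrt(s[nz])
    return out


def normalized_laplacian(G: WeightedGraph) -> np.ndarray:
    """Normalized graph Laplacian ``D^{-1/2} (D - A) D^{-1/2}``.

    Off-diagonal entries are ``-A_ij / sqrt(s_i s_j)``; diagonal entries
    are 1 for nodes with positive strength.  Isolated nodes follow the
    matrix-product convention ``D_ii^{-1/2} = 0``: their row and column
    are identically zero, so they do not take part in diffusion.

    The result is symmetric positive semidefinite with eigenvalues in
    ``[0, 2]``.
    """
    A = _validate_adjacency(G.adjacency)
    s = A.sum(axis=1)
    inv = _inv_sqrt_strengths(s)
    L = -(A * inv[:, None]) * inv[None, :]
    np.fill_diagonal(L, np.where(s > 0, 1.0, 0.0))
    return L


def heat_kernel(G: WeightedGraph, tau: float) -> HeatKernel:
    """Full heat kernel ``expm(-tau * L_norm)`` by spectral decomposition.

    ``L_norm`` is symmetric, so ``expm(-tau L) = V diag(e^{-tau lam}) V.T``
    with ``V`` orthonormal — exact up to eigendecomposition round-off and
    unconditionally stable (all exponents are nonpositive).
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    L = normalized_laplacian(G)
    lam, V = np.linalg.eigh(L)
    H = (V * np.exp(-tau * lam)) @ V.T
    H = (H + H.T) / 2.0  # remove round-off asymmetry
    return HeatKernel(matrix=H, tau=float(tau))


def _taylor_terms(tau: float, tol: float = 1e-14) -> int:
    """Number of Taylor terms so the neglected tail of e^{tau*P}v is < tol.

    The propagator ``P = D^{-1/2} A D^{-1/2}`` has spectral radius <= 1,
    so term j is bounded by ``tau^j / j!``.
    """
    term, j = 1.0, 0
    while True:
        j += 1
        term *= tau / j
        if j > tau and term < tol:
            return j


def heat_kernel_row(
    A: np.ndarray, s: np.ndarray, tau: float, k: int, n_terms: int | None = None
) -> np.ndarray:
    """Row ``k`` of the heat kernel, without forming the full matrix.

    Uses the splitting ``expm(-tau L) = e^{-tau} expm(tau P)`` with
    ``P = D^{-1/2} A D^{-1/2}`` (spectral radius <= 1) and sums the Taylor
    series of ``expm(tau P) e_k`` by repeated matrix-vector products.
    This is the hot path of the rewiring simulation: each product is an
    ``n x n`` gemv, and ~30 of them replace a full eigendecomposition.

    Parameters
    ----------
    A, s
        Adjacency matrix and its row sums (strengths), passed separately
        because the caller maintains ``s`` incrementally.
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    if s[k] == 0:
        # isolated node: zero Laplacian row, so its heat stays put exactly
        v = np.zeros(A.shape[0])
        v[k] = 1.0
        return v
    if n_terms is None:
        n_terms = _taylor_terms(tau)
    inv = _inv_sqrt_strengths(s)
    P = (A * inv[:, None]) * inv[None, :]
    v = np.zeros(A.shape[0])
    v[k] = 1.0
    acc = v.copy()
    term = v
    for j in range(1, n_terms + 1):
        term = (tau / j) * (P @ term)
        acc += term
    return np.exp(-tau) * acc
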