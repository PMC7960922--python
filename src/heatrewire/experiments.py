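"""Simulation campaigns: tau sweeps, transition detection, two-stage runs.

These drive the rewiring simulator across the control parameter tau and
quantify the modular-to-centralized phase transition:

* :func:`tau_sweep` maps Q(tau) and the degree-outlier proportion over a
  tau grid (the curves rise/plateau/fall and follow a sigmoid,
  respectively);
* :func:`find_transition` locates the inflection point tau* of such a
  curve by its largest finite-difference derivative;
* :func:`initial_final_correlation` asks how much of the rewired
  network's modularity is inherited from the random initial network;
* :func:`two_stage` rewires pre-structured networks (4,000 steps at the
  transition interval, then 4,000 more at a test interval) and fits
  ``Q_8000 = alpha * Q_4000 + beta`` — a near-diagonal fit indicates
  robustness, a near-horizontal one specificity, and a low R^2
  flexibility;
* :func:`bootstrap_r2` puts resampling error bars on that R^2.

Every replicate is seeded by a ``SeedSequence`` keyed on
(master seed, tau, replicate index), so any single replicate can be
re-run in isolation, bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import WeightedGraph
from .metrics import detect_communities, outlier_proportion
from .netgen import WeightSpec, generate_initial_network, weight_spec
from .rewiring import RewiringConfig, run_rewiring

__all__ = [
    "TauSweepResult",
    "TwoStageResult",
    "NoTransitionError",
    "replicate_rng",
    "tau_sweep",
    "find_transition",
    "modularity_distributions",
    "initial_final_correlation",
    "two_stage",
    "linear_fit",
    "r_squared",
    "bootstrap_r2",
    "TAU_TRANSITION",
    "TAU_MODULAR",
    "TAU_CENTRALIZED",
]

logger = logging.getLogger(__name__)

#: Transition rewiring intervals (inflection of the outlier sigmoid) per family.
TAU_TRANSITION = {"normal": 4.15, "lognormal": 5.5}
#: Representative modular-regime intervals per family.
TAU_MODULAR = {"normal": 3.0, "lognormal": 4.5}
#: Representative centralized-regime intervals per family.
TAU_CENTRALIZED = {"normal": 5.0, "lognormal": 7.0}


class NoTransitionError(ValueError):
    """The curve is flat: no inflection point can be located."""


def replicate_rng(master_seed: int, tau: float, replicate: int) -> np.random.Generator:
    """Independent, reproducible RNG for one (tau, replicate) cell.

    tau is keyed at millitau resolution so that e.g. 4.15 and 4.25 map to
    distinct streams.
    """
    ss = np.random.SeedSequence((int(master_seed), int(round(tau * 1000)), int(replicate)))
    return np.random.default_rng(ss)


def _resolve_spec(family: str | WeightSpec) -> WeightSpec:
    return family if isinstance(family, WeightSpec) else weight_spec(family)


def _one_replicate(
    spec: WeightSpec,
    tau: float,
    p_random: float,
    steps: int,
    rng: np.random.Generator,
    n: int,
    community_seed: int,
) -> tuple[float, float, float]:
    """(initial Q, final Q, final outlier proportion) for one fresh network."""
    G0 = generate_initial_network(n, spec, rng)
    q0 = detect_communities(G0, seed=community_seed).q
    cfg = RewiringConfig(tau=tau, p_random=p_random, steps=steps)
    res = run_rewiring(G0, cfg, rng=rng)
    if not res.completed:
        logger.warning("run stopped early at step %d", res.steps_completed)
    q1 = detect_communities(res.graph, seed=community_seed + 1).q
    return q0, q1, outlier_proportion(res.graph)


@dataclass
class TauSweepResult:
    """Replicate-level and aggregated Q / outlier curves over a tau grid."""

    tau_grid: np.ndarray
    q_values: np.ndarray          # (n_tau, reps)
    outlier_values: np.ndarray    # (n_tau, reps)

    @property
    def q_mean(self) -> np.ndarray:
        return self.q_values.mean(axis=1)

    @property
    def q_sd(self) -> np.ndarray:
        return self.q_values.std(axis=1, ddof=1)

    @property
    def outlier_mean(self) -> np.ndarray:
        return self.outlier_values.mean(axis=1)

    @property
    def outlier_sd(self) -> np.ndarray:
        return self.outlier_values.std(axis=1, ddof=1)


def tau_sweep(
    family: str | WeightSpec,
    p_random: float,
    tau_grid: np.ndarray,
    reps: int,
    steps: int = 4000,
    seed: int = 0,
    n: int = 100,
) -> TauSweepResult:
    """Final-state Q and outlier proportion across a tau grid.

    For each tau, ``reps`` fresh random networks are generated and
    rewired for ``steps`` steps; communities are detected on each final
    network and the degree-outlier proportion measured against the
    network's own mean degree.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if not np.all(np.diff(tau_grid) > 0):
        raise ValueError("tau grid must be strictly increasing")
    if reps < 2:
        raise ValueError("need at least 2 replicates per tau")
    spec = _resolve_spec(family)
    q = np.empty((len(tau_grid), reps))
    outl = np.empty((len(tau_grid), reps))
    for i, tau in enumerate(tau_grid):
        for rep in range(reps):
            rng = replicate_rng(seed, tau, rep)
            cseed = int(rng.integers(2**31))
            _, q[i, rep], outl[i, rep] = _one_replicate(
                spec, tau, p_random, steps, rng, n, cseed
            )
    return TauSweepResult(tau_grid=tau_grid, q_values=q, outlier_values=outl)


def find_transition(
    tau_grid: np.ndarray, curve: np.ndarray, mode: str = "ascending_sigmoid"
) -> float:
    """Grid point of steepest change of a response curve.

    ``mode="ascending_sigmoid"`` (outlier-proportion curves) returns the
    tau with the largest absolute central-difference derivative;
    ``mode="descending_segment"`` (Q curves, which rise then fall)
    restricts the search to points where the curve is locally decreasing.
    Ties resolve to the smallest tau.  No sub-grid interpolation is done,
    so the grid step bounds the precision of the estimate.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if len(tau_grid) < 3:
        raise ValueError("need at least 3 grid points")
    if mode not in ("ascending_sigmoid", "descending_segment"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.allclose(curve, curve[0]):
        raise NoTransitionError("curve is constant")
    deriv = np.gradient(curve, tau_grid)
    score = np.abs(deriv)
    if mode == "descending_segment":
        descending = deriv < 0
        if not descending.any():
            raise NoTransitionError("curve has no descending segment")
        score = np.where(descending, score, -np.inf)
    best = score.max()
    if np.isclose(best, score.min()):
        logger.warning("derivative is (near-)constant; transition ill-defined")
    # ties -> smallest tau: argmax returns the first maximal index
    return float(tau_grid[int(np.argmax(score >= best - 1e-15 * max(1.0, abs(best))))])


def modularity_distributions(
    family: str | WeightSpec,
    tau_list: np.ndarray,
    reps: int,
    steps: int = 4000,
    seed: int = 0,
    p_random: float = 0.2,
    n: int = 100,
) -> dict[float, np.ndarray]:
    """Replicate final-Q samples at each tau, for histogramming.

    Used to compare modularity distributions at small perturbations
    around the transition interval (tau* +/- {0, 0.1, 0.2}).
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates per tau")
    spec = _resolve_spec(family)
    out: dict[float, np.ndarray] = {}
    for tau in np.asarray(tau_list, dtype=float):
        vals = np.empty(reps)
        for rep in range(reps):
            rng = replicate_rng(seed, tau, rep)
            cseed = int(rng.integers(2**31))
            _, vals[rep], _ = _one_replicate(spec, tau, p_random, steps, rng, n, cseed)
        out[float(tau)] = vals
    return out


def initial_final_correlation(
    family: str | WeightSpec,
    tau: float,
    reps: int,
    steps: int = 4000,
    seed: int = 0,
    p_random: float = 0.2,
    n: int = 100,
) -> tuple[float, np.ndarray]:
    """Pearson correlation between initial and rewired modularity.

    Returns ``(rho, pairs)`` where pairs is a ``(reps, 2)`` array of
    (Q_initial, Q_final).  A strong positive rho means the small random
    biases of the initial network survive rewiring.
    """
    if reps < 3:
        raise ValueError("need at least 3 replicates")
    pairs = np.empty((reps, 2))
    spec = _resolve_spec(family)
    for rep in range(reps):
        rng = replicate_rng(seed, tau, rep)
        cseed = int(rng.integers(2**31))
        q0, q1, _ = _one_replicate(spec, tau, p_random, steps, rng, n, cseed)
        pairs[rep] = (q0, q1)
    if np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    rho = float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])
    return rho, pairs


@dataclass
class TwoStageResult:
    """Paired (Q_4000, Q_8000) samples with the fitted linear relation."""

    tau_transition: float
    tau_test: float
    q_first: np.ndarray
    q_second: np.ndarray
    alpha: float = field(init=False)
    beta: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha, self.beta = linear_fit(self.q_first, self.q_second)
        self.r2 = r_squared(self.q_first, self.q_second)

    @property
    def pairs(self) -> np.ndarray:
        return np.column_stack([self.q_first, self.q_second])


def two_stage(
    family: str | WeightSpec,
    tau_transition: float,
    tau_test: float,
    reps: int,
    r1: int = 4000,
    r2: int = 4000,
    seed: int = 0,
    p_random: float = 0.2,
    n: int = 100,
) -> TwoStageResult:
    """Rewire at the transition interval, then keep rewiring at tau_test.

    Stage 1 (``r1`` steps at ``tau_transition``) manufactures networks
    spanning the whole modular-centralized range; stage 2 (``r2`` steps
    at ``tau_test``) probes whether further rewiring preserves
    (robustness), overwrites (specificity), or scrambles (flexibility)
    that structure.  The result carries the OLS fit of Q_8000 on Q_4000.
    """
    if reps < 3:
        raise ValueError("need at least 3 replicates")
    spec = _resolve_spec(family)
    q_first = np.empty(reps)
    q_second = np.empty(reps)
    for rep in range(reps):
        rng = replicate_rng(seed, tau_transition, rep)
        cseed = int(rng.integers(2**31))
        G0 = generate_initial_network(n, spec, rng)
        stage1 = run_rewiring(
            G0, RewiringConfig(tau=tau_transition, p_random=p_random, steps=r1), rng=rng
        )
        q_first[rep] = detect_communities(stage1.graph, seed=cseed).q
        stage2 = run_rewiring(
            stage1.graph,
            RewiringConfig(tau=tau_test, p_random=p_random, steps=r2),
            rng=rng,
        )
        q_second[rep] = detect_communities(stage2.graph, seed=cseed + 1).q
    return TwoStageResult(
        tau_transition=tau_transition,
        tau_test=tau_test,
        q_first=q_first,
        q_second=q_second,
    )


def linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary-least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two same-length vectors with >= 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("need >= 2 points with variance on both sides")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def bootstrap_r2(
    pairs: np.ndarray,
    sample_size: int = 100,
    pool_size: int = 200,
    reps_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap mean and SD of R^2 over (Q_4000, Q_8000) pairs.

    A pool of ``pool_size`` pairs is fixed (subsampled without
    replacement if more are supplied); each bootstrap replicate draws
    ``sample_size`` pairs from the pool with replacement and computes
    R^2.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    rng = np.random.default_rng(seed)
    if pairs.shape[0] < pool_size:
        raise ValueError(
            f"need at least pool_size={pool_size} pairs, got {pairs.shape[0]}"
        )
    if pairs.shape[0] > pool_size:
        pool = pairs[rng.choice(pairs.shape[0], size=pool_size, replace=False)]
    else:
        pool = pairs
    vals = np.empty(reps_boot)
    for b in range(reps_boot):
        idx = rng.integers(0, pool_size, size=sample_size)
        x, y = pool[idx, 0], pool[idx, 1]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            vals[b] = 1.0  # degenerate resample: perfectly (trivially) linear
        else:
            vals[b] = np.corrcoef(x, y)[0, 1] ** 2
    return float(vals.mean()), float(vals.std(ddof=1))
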