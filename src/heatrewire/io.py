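"""File formats, run configuration, and run manifests.

Graphs travel as either a weighted edge list (TSV: ``u  v  w`` with
0-based integer node ids, one undirected edge per line, u < v) or a
dense adjacency matrix (CSV).  Weights are serialized with 17
significant digits so write -> read is an exact float round-trip.

A :class:`RunConfig` mirrors the CLI flags; a :class:`RunManifest`
(written as JSON next to every output) records the full parameter set,
seed, and library versions needed to re-run a result bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy

from .graph import WeightedGraph

__all__ = [
    "ConfigError",
    "GraphFormatError",
    "RunConfig",
    "RunManifest",
    "load_config",
    "read_graph",
    "write_graph",
    "read_edge_tsv",
    "write_edge_tsv",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "write_manifest",
]


class ConfigError(ValueError):
    """A run-configuration file failed validation."""


class GraphFormatError(ValueError):
    """A graph file is malformed; the message names the offending line."""


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation parameters (defaults match the standard setup)."""

    n: int = 100
    weight_family: str = "normal"
    mu: float | None = None
    sigma: float | None = None
    tau: float = 4.15
    p_random: float = 0.2
    steps: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError(f"n must be >= 2, got {self.n}")
        if self.weight_family not in ("normal", "lognormal"):
            raise ConfigError(f"unknown weight_family {self.weight_family!r}")
        if self.mu is None:
            object.__setattr__(self, "mu", 1.0 if self.weight_family == "normal" else 0.0)
        if self.sigma is None:
            object.__setattr__(
                self, "sigma", 0.25 if self.weight_family == "normal" else 1.0
            )
        if not self.sigma > 0:
            raise ConfigError(f"sigma must be positive, got {self.sigma}")
        if not self.tau > 0:
            raise ConfigError(f"tau must be positive, got {self.tau}")
        if not 0.0 <= self.p_random <= 1.0:
            raise ConfigError(f"p_random must be in [0, 1], got {self.p_random}")
        if self.steps < 0:
            raise ConfigError(f"steps must be >= 0, got {self.steps}")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be an object")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2)
        fh.write("\n")


# -- graph readers / writers ---------------------------------------------


def read_edge_tsv(path: str | Path, n: int | None = None) -> WeightedGraph:
    """Read a weighted edge list (``u<TAB>v<TAB>w`` per line).

    ``n`` defaults to ``max node id + 1``; pass it explicitly to keep
    trailing isolated nodes.
    """
    path = Path(path)
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                u, v, w = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise GraphFormatError(f"{path}:{lineno}: {exc}") from exc
            if u == v:
                raise GraphFormatError(f"{path}:{lineno}: self-loop on node {u}")
            if u < 0 or v < 0:
                raise GraphFormatError(f"{path}:{lineno}: negative node id")
            if w < 0:
                raise GraphFormatError(f"{path}:{lineno}: negative weight {w}")
            rows.append((u, v, w))
    if not rows:
        raise GraphFormatError(f"{path}: no edges")
    size = max(max(u, v) for u, v, _ in rows) + 1
    if n is not None:
        if n < size:
            raise GraphFormatError(f"{path}: node id {size - 1} >= n={n}")
        size = n
    A = np.zeros((size, size))
    for u, v, w in rows:
        A[u, v] = w
        A[v, u] = w
    return WeightedGraph(A)


def write_edge_tsv(G: WeightedGraph, path: str | Path) -> None:
    """Write the canonical edge list: sorted, one undirected edge, u < v."""
    u, v, w = G.edges()
    with open(path, "w") as fh:
        for a, b, x in zip(u.tolist(), v.tolist(), w.tolist()):
            fh.write(f"{a}\t{b}\t{x:.17g}\n")


def read_adjacency_csv(path: str | Path) -> WeightedGraph:
    """Read a dense adjacency matrix (n lines of n comma-separated values)."""
    path = Path(path)
    try:
        A = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise GraphFormatError(f"{path}: {exc}") from exc
    try:
        return WeightedGraph(A)
    except ValueError as exc:
        raise GraphFormatError(f"{path}: {exc}") from exc


def write_adjacency_csv(G: WeightedGraph, path: str | Path) -> None:
    np.savetxt(path, G.adjacency, delimiter=",", fmt="%.17g")


def read_graph(path: str | Path, fmt: str = "edge_tsv", n: int | None = None) -> WeightedGraph:
    if fmt == "edge_tsv":
        return read_edge_tsv(path, n=n)
    if fmt == "adjacency_csv":
        return read_adjacency_csv(path)
    raise ValueError(f"unknown graph format {fmt!r}")


def write_graph(G: WeightedGraph, path: str | Path, fmt: str = "edge_tsv") -> None:
    if fmt == "edge_tsv":
        write_edge_tsv(G, path)
    elif fmt == "adjacency_csv":
        write_adjacency_csv(G, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


# -- manifests ------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to re-run an invocation bit-identically."""

    command: str
    parameters: dict
    timestamp: str = ""
    versions: dict = dataclasses.field(default_factory=dict)
    inputs: list[str] = dataclasses.field(default_factory=list)
    outputs: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        if not self.versions:
            from . import __version__

            self.versions = {
                "heatrewire": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "python": platform.python_version(),
            }


def write_manifest(manifest: RunManifest, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "manifest.json"
    with open(out, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")
    return out
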