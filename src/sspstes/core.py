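"""Shared data model, CSV ingestion and network serialization.

The universal input is a :class:`TimeSeriesMatrix` — a named multivariate
time series with rows as time points and columns as variables.  The final
output of the pipeline is a :class:`DirectedWeightedNetwork` whose edges
carry an information-flow weight and the prediction lag at which the flow
peaked.  :class:`RunConfig` collects every tunable parameter of the
method with the defaults used throughout the benchmarks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "RunConfig",
    "Edge",
    "DirectedWeightedNetwork",
    "ValidationError",
    "read_timeseries_csv",
    "write_network",
    "read_network",
    "read_adjacency_csv",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A k x n multivariate time series with unique column names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix (time x variables)")
        k, n = values.shape
        if k < 2:
            raise ValidationError(f"need at least 2 time points, got {k}")
        if len(self.names) != n:
            raise ValidationError(
                f"{len(self.names)} names for {n} columns"
            )
        if len(set(self.names)) != n:
            raise ValidationError("variable names must be unique")
        if any(not name for name in self.names):
            raise ValidationError("variable names must be non-empty")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at row {bad[0] + 1}, column "
                f"'{self.names[bad[1]]}'"
            )

    @property
    def k(self) -> int:
        """Number of time points."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of variables."""
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the inference pipeline.

    Defaults reproduce the benchmark settings: shuffle amplitude A = 1.0,
    embedding dimension m = 3 with delay 1, maximum prediction lag
    tm = 10, sm = 99 surrogates, Granger significance level 0.01,
    bidirectional dominance factor 0.4, and edge weights scaled by 100
    (raw transfer-entropy values are small; the scale matches how they
    are conventionally plotted and tabulated).

    ``conditioning`` selects the sweep statistic: ``"pairwise"``
    (default) uses the plain symbolic transfer entropy of each ordered
    pair; ``"full"`` additionally conditions on the rank vectors of all
    remaining variables.  The fully conditioned plug-in estimator is
    faithful to the partial-transfer-entropy definition but is strongly
    bias-dominated at m = 3 with series of ~1000 points (its joint
    state space far exceeds the sample), so the pairwise statistic is
    the default; the surrogate test then supplies the control for
    indirect-correlation inflation, followed by the filter cascade.
    """

    amplitude_A: float = 1.0
    m: int = 3
    tau_embed: int = 1
    tm: int = 10
    sm: int = 99
    gc_alpha: float = 0.01
    bidir_factor: float = 0.4
    weight_scale: float = 100.0
    seed: int = 0
    conditioning: str = "pairwise"

    def __post_init__(self) -> None:
        if self.conditioning not in ("pairwise", "full"):
            raise ValidationError(
                f"conditioning must be 'pairwise' or 'full', got {self.conditioning!r}"
            )
        if self.amplitude_A < 0:
            raise ValidationError("amplitude_A must be >= 0")
        if self.m < 2:
            raise ValidationError("embedding dimension m must be >= 2")
        if self.tau_embed < 1:
            raise ValidationError("tau_embed must be >= 1")
        if self.tm < 1:
            raise ValidationError("tm must be >= 1")
        if self.sm < 1:
            raise ValidationError("at least one surrogate is required (sm >= 1)")
        if not 0 < self.gc_alpha < 1:
            raise ValidationError("gc_alpha must be in (0, 1)")
        if not 0 < self.bidir_factor <= 1:
            raise ValidationError("bidir_factor must be in (0, 1]")
        if self.weight_scale <= 0:
            raise ValidationError("weight_scale must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float
    lag: int


@dataclass(frozen=True)
class DirectedWeightedNetwork:
    """Directed network with per-edge weight and lag annotation."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        node_set = set(self.nodes)
        for e in self.edges:
            if e.source == e.target:
                raise ValidationError(f"self-loop on '{e.source}' not allowed")
            if e.source not in node_set or e.target not in node_set:
                raise ValidationError(f"edge {e.source}->{e.target} off the node set")
            if not e.weight > 0:
                raise ValidationError(
                    f"edge {e.source}->{e.target} has non-positive weight"
                )
            if e.lag < 1:
                raise ValidationError(f"edge {e.source}->{e.target} has lag < 1")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, weight=float(e.weight), lag=int(e.lag))
        return g

    def adjacency(self) -> pd.DataFrame:
        """Dense weight matrix, zero meaning no edge."""
        mat = pd.DataFrame(
            0.0, index=list(self.nodes), columns=list(self.nodes)
        )
        for e in self.edges:
            mat.loc[e.source, e.target] = e.weight
        return mat


def read_timeseries_csv(path: str | Path) -> TimeSeriesMatrix:
    """Read a header+numeric CSV into a :class:`TimeSeriesMatrix`.

    The first row must name the variables; every following cell must be
    numeric and present — missing values are rejected rather than
    imputed because rank symbolization has no meaningful fill value.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n\r")
    names = [c.strip() for c in header.split(",")]
    if len(names) != len(set(names)):
        raise ValidationError(f"{path}: duplicate column names in header")
    df = pd.read_csv(path, header=0, dtype=str, skipinitialspace=True)
    df.columns = names  # undo pandas' dedup mangling
    if len(names) < 2:
        raise ValidationError(
            f"{path}: pairwise analysis needs at least 2 columns, got {len(names)}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            row = int(bad[0]) + 2  # 1-based, counting the header row
            raise ValidationError(
                f"{path}: non-numeric or missing value at row {row}, "
                f"column '{col}'"
            )
        values[:, j] = parsed.to_numpy()
    return TimeSeriesMatrix(values=values, names=tuple(names))


def write_timeseries_csv(ts: TimeSeriesMatrix, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.names)).to_csv(path, index=False)


_EDGELIST_HEADER = "source\ttarget\tweight\tlag"


def write_network(
    net: DirectedWeightedNetwork, path: str | Path, format: str = "edgelist"
) -> None:
    """Serialize a network as ``edgelist`` (TSV), ``graphml`` or
    ``adjacency-csv`` (dense weight matrix with row/column labels)."""
    path = Path(path)
    if format == "edgelist":
        lines = [_EDGELIST_HEADER]
        for e in net.edges:
            lines.append(f"{e.source}\t{e.target}\t{e.weight!r}\t{e.lag}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "adjacency-csv":
        net.adjacency().to_csv(path, index_label="")
    else:
        raise ValidationError(f"unknown network format: {format!r}")


def read_network(path: str | Path, format: str = "edgelist") -> DirectedWeightedNetwork:
    """Read back an ``edgelist`` or ``graphml`` file written by
    :func:`write_network`; the round trip is the identity on content."""
    path = Path(path)
    if format == "edgelist":
        lines = path.read_text().splitlines()
        if not lines or lines[0] != _EDGELIST_HEADER:
            raise ValidationError(f"{path}: not an edge-list file")
        edges = []
        nodes: list[str] = []
        for line in lines[1:]:
            if not line.strip():
                continue
            src, tgt, w, lag = line.split("\t")
            edges.append(Edge(src, tgt, float(w), int(lag)))
            for v in (src, tgt):
                if v not in nodes:
                    nodes.append(v)
        return DirectedWeightedNetwork(nodes=tuple(nodes), edges=tuple(edges))
    elif format == "graphml":
        g = nx.read_graphml(path)
        edges = tuple(
            Edge(str(u), str(v), float(d["weight"]), int(d["lag"]))
            for u, v, d in g.edges(data=True)
        )
        return DirectedWeightedNetwork(nodes=tuple(str(v) for v in g.nodes), edges=edges)
    else:
        raise ValidationError(f"unknown network format for reading: {format!r}")


def read_adjacency_csv(path: str | Path) -> pd.DataFrame:
    """Read a dense weight matrix written with format='adjacency-csv'."""
    return pd.read_csv(path, index_col=0)
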