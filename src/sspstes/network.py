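"""Final weighted, directed, lag-annotated network assembly."""

from __future__ import annotations

import numpy as np

from .core import DirectedWeightedNetwork, Edge, RunConfig
from .edge_filter import StrongEdgeMatrix
from .entropy import PSTETensor

__all__ = ["assign_weights", "summarize"]


def assign_weights(
    strong: StrongEdgeMatrix,
    tensor: PSTETensor,
    best_lag: np.ndarray,
    cfg: RunConfig,
) -> DirectedWeightedNetwork:
    """Attach weights and lags to the strong edges.

    The weight of i->j is ``weight_scale`` times the maximum over
    prediction lags of the original-data PSTE for that pair; the lag is
    the arg-max recorded at candidate-identification time.
    """
    strengths = tensor.original_strengths()
    edges = []
    for i, j in strong.pairs():
        edges.append(
            Edge(
                source=strong.names[i],
                target=strong.names[j],
                weight=float(cfg.weight_scale * strengths[i, j]),
                lag=int(best_lag[i, j]),
            )
        )
    return DirectedWeightedNetwork(nodes=strong.names, edges=tuple(edges))


def summarize(net: DirectedWeightedNetwork) -> str:
    """Human-readable report: edges by descending weight, then degrees."""
    lines = [f"Nodes: {len(net.nodes)}   Edges: {len(net.edges)}", ""]
    if net.edges:
        lines.append(f"{'source':<12}{'target':<12}{'weight':>10}{'lag':>6}")
        for e in sorted(net.edges, key=lambda e: -e.weight):
            lines.append(f"{e.source:<12}{e.target:<12}{e.weight:>10.2f}{e.lag:>6}")
        lines.append("")
    out_deg = {v: 0 for v in net.nodes}
    in_deg = {v: 0 for v in net.nodes}
    for e in net.edges:
        out_deg[e.source] += 1
        in_deg[e.target] += 1
    lines.append(f"{'node':<12}{'out-degree':>12}{'in-degree':>12}")
    for v in net.nodes:
        lines.append(f"{v:<12}{out_deg[v]:>12}{in_deg[v]:>12}")
    return "\n".join(lines)
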