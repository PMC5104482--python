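"""End-to-end inference: time series in, weighted directed network out.

The stages are: small-shuffle surrogate generation, rank
symbolization, the PSTE sweep over datasets x lags x ordered pairs,
spectrum assembly, surrogate-outlier candidate identification, the
DPI / bidirectional / Granger filter cascade, and weight assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import DirectedWeightedNetwork, RunConfig, TimeSeriesMatrix
from .edge_filter import StrongEdgeMatrix, filter_cascade
from .entropy import PSTETensor, pste_sweep
from .network import assign_weights
from .spectrum import CandidateMatrix, Spectrum, build_spectra, identify_candidates
from .surrogates import make_surrogate_set

__all__ = ["InferenceResult", "infer_network"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceResult:
    """Everything the pipeline computes, for inspection and plotting."""

    network: DirectedWeightedNetwork
    spectra: dict[tuple[str, str], Spectrum]
    candidates: CandidateMatrix
    strong: StrongEdgeMatrix
    tensor: PSTETensor
    config: RunConfig


def infer_network(ts: TimeSeriesMatrix, cfg: RunConfig) -> InferenceResult:
    """Run the full pipeline on one multivariate time series."""
    logger.info(
        "input: %d time points x %d variables; config: %s", ts.k, ts.n, cfg
    )
    surrogates = make_surrogate_set(ts, cfg)
    logger.info("generated %d small-shuffle surrogates (A=%g)", surrogates.sm, cfg.amplitude_A)
    tensor = pste_sweep(surrogates, cfg)
    logger.info(
        "PSTE sweep: %d datasets x %d lags x %d variables",
        tensor.n_datasets, tensor.tm, tensor.n,
    )
    spectra = build_spectra(tensor)
    candidates = identify_candidates(spectra)
    logger.info("candidate relationships: %d", int(candidates.a.sum()))
    strengths = tensor.original_strengths()
    strong = filter_cascade(candidates, strengths, ts, cfg)
    logger.info(
        "strong relationships after filter cascade: %d", int(strong.a.sum())
    )
    network = assign_weights(strong, tensor, candidates.best_lag, cfg)
    return InferenceResult(
        network=network,
        spectra=spectra,
        candidates=candidates,
        strong=strong,
        tensor=tensor,
        config=cfg,
    )
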