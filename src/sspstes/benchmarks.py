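"""Benchmark generators with known ground truth, and scoring.

Two coupled stochastic systems serve as test beds.  The *linear* system
is a 5-variable autoregressive network driven by i.i.d. N(0,1) noise:

    x1(t) = 1.3 + 0.2 x1(t-1) + 0.4 x2(t-4) + 0.4 x4(t-7) + r1(t)
    x2(t) = 20  + 0.6 x2(t-1) - 0.4 x2(t-6)               + r2(t)
    x3(t) = 2.2 + 0.2 x1(t-2) + 0.5 x3(t-1) + 0.3 x4(t-9) + r3(t)
    x4(t) = 1.5 + 0.7 x1(t-2) + 0.3 x4(t-1)               + r4(t)
    x5(t) = 10  + 0.9 x4(t-4) + 0.1 x5(t-1)               + r5(t)

The *nonlinear* system has 6 variables with square, square-root and
product couplings:

    x1(t) = 2.7 + 0.5 x1(t-1)                               + r1(t)
    x2(t) = 1.7 + 0.2 x2(t-1) + 0.3 x1(t-1)^2               + r2(t)
    x3(t) = 1.4 + 0.15 x3(t-1) + 0.8 sqrt(x1(t-3))          + r3(t)
    x4(t) = 2.1 + 0.25 x4(t-1) - 0.7 x5(t-2) + 0.6 x3(t-4)  + r4(t)
    x5(t) = 1.5 + 0.35 x5(t-1) - 0.5 x4(t-3)                + r5(t)
    x6(t) = 1.3 + 0.2 x6(t-1) + 0.4 x2(t-1) x3(t-5)         + r6(t)

Cross-variable coupling terms define the ground-truth directed edges
and their lags (autoregressive self-terms are not counted as edges).
Inferred networks are scored by precision, sensitivity and PTL — the
precision of time-lag identification among correctly inferred edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import DirectedWeightedNetwork, RunConfig, TimeSeriesMatrix
from .edge_filter import granger_matrix
from .entropy import pste_sweep
from .pipeline import InferenceResult, infer_network

__all__ = [
    "GroundTruthNetwork",
    "EvaluationResult",
    "ExperimentResult",
    "LINEAR_TRUTH",
    "NONLINEAR_TRUTH",
    "SimulationError",
    "linear_fixed_point",
    "nonlinear_fixed_point",
    "simulate_linear",
    "simulate_nonlinear",
    "simulate",
    "evaluate",
    "evaluate_edges",
    "run_experiment",
    "method_results",
    "compare_methods",
]

logger = logging.getLogger(__name__)

_SIM_STREAM = 0x51D
_REP_STREAM = 0x0ED


class SimulationError(RuntimeError):
    """Raised when a simulated trajectory diverges."""


@dataclass(frozen=True)
class GroundTruthNetwork:
    """True cross-variable directed edges with their coupling lags."""

    edges: frozenset[tuple[str, str, int]]

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _ in self.edges}

    @property
    def lag_of(self) -> dict[tuple[str, str], int]:
        return {(s, t): lag for s, t, lag in self.edges}


LINEAR_TRUTH = GroundTruthNetwork(
    edges=frozenset(
        {
            ("x2", "x1", 4),
            ("x4", "x1", 7),
            ("x1", "x3", 2),
            ("x4", "x3", 9),
            ("x1", "x4", 2),
            ("x4", "x5", 4),
        }
    )
)

NONLINEAR_TRUTH = GroundTruthNetwork(
    edges=frozenset(
        {
            ("x1", "x2", 1),
            ("x1", "x3", 3),
            ("x3", "x4", 4),
            ("x5", "x4", 2),
            ("x4", "x5", 3),
            ("x2", "x6", 1),
            ("x3", "x6", 5),
        }
    )
)


def linear_fixed_point() -> np.ndarray:
    """Deterministic (noise-free) equilibrium of the linear system."""
    # (I - B) x = c where B sums each variable's coefficients
    B = np.zeros((5, 5))
    c = np.array([1.3, 20.0, 2.2, 1.5, 10.0])
    B[0, 0], B[0, 1], B[0, 3] = 0.2, 0.4, 0.4
    B[1, 1] = 0.6 - 0.4
    B[2, 0], B[2, 2], B[2, 3] = 0.2, 0.5, 0.3
    B[3, 0], B[3, 3] = 0.7, 0.3
    B[4, 3], B[4, 4] = 0.9, 0.1
    return np.linalg.solve(np.eye(5) - B, c)


def nonlinear_fixed_point() -> np.ndarray:
    """Deterministic equilibrium of the nonlinear system (solved
    numerically)."""

    def residual(x):
        x1, x2, x3, x4, x5, x6 = x
        return [
            2.7 + 0.5 * x1 - x1,
            1.7 + 0.2 * x2 + 0.3 * x1**2 - x2,
            1.4 + 0.15 * x3 + 0.8 * math.sqrt(max(x1, 0.0)) - x3,
            2.1 + 0.25 * x4 - 0.7 * x5 + 0.6 * x3 - x4,
            1.5 + 0.35 * x5 - 0.5 * x4 - x5,
            1.3 + 0.2 * x6 + 0.4 * x2 * x3 - x6,
        ]

    sol = optimize.fsolve(residual, np.full(6, 1.0), full_output=False)
    return np.asarray(sol)


_LINEAR_MAX_LAG = 9
_NONLINEAR_MAX_LAG = 5
_DIVERGENCE_BOUND = 1e6


def simulate_linear(
    k: int,
    seed: int = 0,
    burn_in: int = 100,
    *,
    noise_std: float = 1.0,
    init: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """Simulate the 5-variable linear system.

    ``burn_in`` leading points are discarded.  Initial history defaults
    to the deterministic fixed point perturbed by N(0, noise_std) draws,
    so ``noise_std=0`` yields the constant equilibrium trajectory.
    """
    if burn_in < _LINEAR_MAX_LAG:
        raise ValueError(f"burn_in must be >= {_LINEAR_MAX_LAG}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SIM_STREAM,)))
    total = _LINEAR_MAX_LAG + burn_in + k
    x = np.empty((total, 5))
    fp = linear_fixed_point()
    if init is None:
        x[:_LINEAR_MAX_LAG] = fp + noise_std * rng.standard_normal((_LINEAR_MAX_LAG, 5))
    else:
        x[:_LINEAR_MAX_LAG] = np.asarray(init, dtype=float)
    r = noise_std * rng.standard_normal((total, 5))
    for t in range(_LINEAR_MAX_LAG, total):
        x[t, 0] = 1.3 + 0.2 * x[t - 1, 0] + 0.4 * x[t - 4, 1] + 0.4 * x[t - 7, 3] + r[t, 0]
        x[t, 1] = 20.0 + 0.6 * x[t - 1, 1] - 0.4 * x[t - 6, 1] + r[t, 1]
        x[t, 2] = 2.2 + 0.2 * x[t - 2, 0] + 0.5 * x[t - 1, 2] + 0.3 * x[t - 9, 3] + r[t, 2]
        x[t, 3] = 1.5 + 0.7 * x[t - 2, 0] + 0.3 * x[t - 1, 3] + r[t, 3]
        x[t, 4] = 10.0 + 0.9 * x[t - 4, 3] + 0.1 * x[t - 1, 4] + r[t, 4]
    return TimeSeriesMatrix(
        values=x[_LINEAR_MAX_LAG + burn_in :],
        names=("x1", "x2", "x3", "x4", "x5"),
    )


def simulate_nonlinear(
    k: int,
    seed: int = 0,
    burn_in: int = 100,
    *,
    noise_std: float = 1.0,
    init: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """Simulate the 6-variable nonlinear system.

    The square-root argument x1(t-3) can be pushed negative by noise;
    it is clipped at zero inside the root and the clip rate is logged.
    Trajectories exceeding 1e6 in magnitude abort with
    :class:`SimulationError`.
    """
    if burn_in < _NONLINEAR_MAX_LAG:
        raise ValueError(f"burn_in must be >= {_NONLINEAR_MAX_LAG}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SIM_STREAM,)))
    total = _NONLINEAR_MAX_LAG + burn_in + k
    x = np.empty((total, 6))
    fp = nonlinear_fixed_point()
    if init is None:
        x[:_NONLINEAR_MAX_LAG] = fp + noise_std * rng.standard_normal(
            (_NONLINEAR_MAX_LAG, 6)
        )
    else:
        x[:_NONLINEAR_MAX_LAG] = np.asarray(init, dtype=float)
    r = noise_std * rng.standard_normal((total, 6))
    clipped = 0
    for t in range(_NONLINEAR_MAX_LAG, total):
        x1_arg = x[t - 3, 0]
        if x1_arg < 0:
            clipped += 1
            x1_arg = 0.0
        x[t, 0] = 2.7 + 0.5 * x[t - 1, 0] + r[t, 0]
        x[t, 1] = 1.7 + 0.2 * x[t - 1, 1] + 0.3 * x[t - 1, 0] ** 2 + r[t, 1]
        x[t, 2] = 1.4 + 0.15 * x[t - 1, 2] + 0.8 * math.sqrt(x1_arg) + r[t, 2]
        x[t, 3] = 2.1 + 0.25 * x[t - 1, 3] - 0.7 * x[t - 2, 4] + 0.6 * x[t - 4, 2] + r[t, 3]
        x[t, 4] = 1.5 + 0.35 * x[t - 1, 4] - 0.5 * x[t - 3, 3] + r[t, 4]
        x[t, 5] = 1.3 + 0.2 * x[t - 1, 5] + 0.4 * x[t - 1, 1] * x[t - 5, 2] + r[t, 5]
        if np.abs(x[t]).max() > _DIVERGENCE_BOUND:
            raise SimulationError(
                f"nonlinear trajectory diverged at step {t} (seed {seed})"
            )
    if clipped:
        logger.info(
            "sqrt argument clipped at 0 in %d of %d steps", clipped, total
        )
    return TimeSeriesMatrix(
        values=x[_NONLINEAR_MAX_LAG + burn_in :],
        names=("x1", "x2", "x3", "x4", "x5", "x6"),
    )


_SYSTEMS = {
    "linear": (simulate_linear, LINEAR_TRUTH),
    "nonlinear": (simulate_nonlinear, NONLINEAR_TRUTH),
}


def simulate(system: str, k: int, seed: int = 0, burn_in: int = 100) -> TimeSeriesMatrix:
    if system not in _SYSTEMS:
        raise ValueError(f"unknown system {system!r}; choose from {sorted(_SYSTEMS)}")
    sim, _ = _SYSTEMS[system]
    return sim(k, seed, burn_in)


def truth_of(system: str) -> GroundTruthNetwork:
    if system not in _SYSTEMS:
        raise ValueError(f"unknown system {system!r}; choose from {sorted(_SYSTEMS)}")
    return _SYSTEMS[system][1]


@dataclass(frozen=True)
class EvaluationResult:
    """Edge-set and lag scores of one inferred network against truth."""

    TP: int
    FP: int
    FN: int
    TPL: int
    FPL: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def ptl(self) -> float:
        return self.TPL / (self.TPL + self.FPL) if self.TPL + self.FPL else float("nan")


def evaluate_edges(
    edges: set[tuple[str, str]],
    truth: GroundTruthNetwork,
    lags: dict[tuple[str, str], int] | None = None,
) -> EvaluationResult:
    """Score an inferred edge set (optionally lag-annotated) against
    ground truth.  TP/FP/FN ignore lags; TPL/FPL split the true
    positives by whether the inferred lag matches the coupling lag."""
    true_set = truth.edge_set
    tp_edges = edges & true_set
    TP = len(tp_edges)
    FP = len(edges - true_set)
    FN = len(true_set - edges)
    TPL = FPL = 0
    if lags is not None:
        truth_lags = truth.lag_of
        for e in tp_edges:
            if lags.get(e) == truth_lags[e]:
                TPL += 1
            else:
                FPL += 1
    return EvaluationResult(TP=TP, FP=FP, FN=FN, TPL=TPL, FPL=FPL)


def evaluate(
    inferred: DirectedWeightedNetwork, truth: GroundTruthNetwork
) -> EvaluationResult:
    lags = {(e.source, e.target): e.lag for e in inferred.edges}
    return evaluate_edges(inferred.edge_set, truth, lags)


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replicate scores of a benchmark experiment."""

    system: str
    results: tuple[EvaluationResult, ...]
    networks: tuple[DirectedWeightedNetwork, ...]

    def table(self) -> pd.DataFrame:
        """Replicate rows plus an Average row, two-decimal rounding.

        Replicates with no predicted edges have undefined precision;
        they are reported as NaN and excluded from the average."""
        rows = []
        for i, r in enumerate(self.results, start=1):
            rows.append(
                {
                    "ID": str(i),
                    "Precision": round(r.precision, 2) if np.isfinite(r.precision) else np.nan,
                    "Sensitivity": round(r.sensitivity, 2),
                    "PTL": round(r.ptl, 2) if np.isfinite(r.ptl) else np.nan,
                }
            )
        df = pd.DataFrame(rows)
        avg = {
            "ID": "Average",
            "Precision": round(self.mean_precision, 2),
            "Sensitivity": round(self.mean_sensitivity, 2),
            "PTL": round(self.mean_ptl, 2),
        }
        return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)

    @property
    def mean_precision(self) -> float:
        vals = [r.precision for r in self.results if np.isfinite(r.precision)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([r.sensitivity for r in self.results]))

    @property
    def mean_ptl(self) -> float:
        vals = [r.ptl for r in self.results if np.isfinite(r.ptl)]
        return float(np.mean(vals)) if vals else float("nan")


def _replicate_seeds(cfg: RunConfig, replicates: int) -> list[tuple[int, int]]:
    """(simulation seed, pipeline seed) per replicate, all below 2**31,
    derived from the master seed so replicates are independent."""
    out = []
    for rep in range(replicates):
        ss = np.random.SeedSequence(cfg.seed, spawn_key=(_REP_STREAM, rep))
        sim_seed, pipe_seed = (int(v) % 2**31 for v in ss.generate_state(2))
        out.append((sim_seed, pipe_seed))
    return out


def run_experiment(
    system: str,
    replicates: int,
    cfg: RunConfig,
    k: int = 1000,
) -> ExperimentResult:
    """Simulate ``replicates`` independent datasets, run the full
    pipeline on each (fresh noise and fresh initial conditions), and
    score against ground truth."""
    truth = truth_of(system)
    results = []
    networks = []
    for sim_seed, pipe_seed in _replicate_seeds(cfg, replicates):
        ts = simulate(system, k, seed=sim_seed)
        res = infer_network(ts, cfg.replace(seed=pipe_seed))
        ev = evaluate(res.network, truth)
        if res.network.edges == ():
            logger.warning("replicate produced no edges; precision undefined")
        results.append(ev)
        networks.append(res.network)
    return ExperimentResult(
        system=system, results=tuple(results), networks=tuple(networks)
    )


def _threshold_edges(
    ts: TimeSeriesMatrix, cfg: RunConfig, condition: bool
) -> set[tuple[str, str]]:
    """STE/PSTE mean-threshold baseline: edge wherever the pair's
    max-over-lags entropy on the original data exceeds the mean of all
    pairs' values."""
    tensor = pste_sweep(ts, cfg, condition=condition)
    strengths = tensor.original_strengths()
    off = strengths[~np.eye(ts.n, dtype=bool)]
    thresh = float(np.mean(off))
    edges = set()
    for i in range(ts.n):
        for j in range(ts.n):
            if i != j and strengths[i, j] > thresh:
                edges.add((ts.names[i], ts.names[j]))
    return edges


def _gc_edges(ts: TimeSeriesMatrix, cfg: RunConfig) -> set[tuple[str, str]]:
    gc = granger_matrix(ts, cfg)
    return {
        (ts.names[i], ts.names[j]) for (i, j), res in gc.items() if res.significant
    }


def method_results(
    system: str,
    replicates: int,
    cfg: RunConfig,
    k: int = 1000,
) -> dict[str, tuple[EvaluationResult, ...]]:
    """Score GC, STE-threshold, PSTE-threshold and the full SSPSTES
    pipeline on the same simulated datasets.  The GC baseline keeps
    every significant pairwise Granger test; the STE/PSTE baselines
    keep pairs whose max-over-lags statistic exceeds the mean over all
    pairs (PSTE = the fully conditioned variant)."""
    truth = truth_of(system)
    per_method: dict[str, list[EvaluationResult]] = {
        "GC": [], "STE": [], "PSTE": [], "SSPSTES": []
    }
    for sim_seed, pipe_seed in _replicate_seeds(cfg, replicates):
        ts = simulate(system, k, seed=sim_seed)
        per_method["GC"].append(evaluate_edges(_gc_edges(ts, cfg), truth))
        per_method["STE"].append(
            evaluate_edges(_threshold_edges(ts, cfg, condition=False), truth)
        )
        per_method["PSTE"].append(
            evaluate_edges(_threshold_edges(ts, cfg, condition=True), truth)
        )
        res = infer_network(ts, cfg.replace(seed=pipe_seed))
        per_method["SSPSTES"].append(evaluate(res.network, truth))
    return {m: tuple(v) for m, v in per_method.items()}


def compare_methods(
    system: str,
    replicates: int,
    cfg: RunConfig,
    k: int = 1000,
) -> pd.DataFrame:
    """Mean precision and sensitivity per method on shared datasets."""
    rows = []
    for method, results in method_results(system, replicates, cfg, k).items():
        prec = [r.precision for r in results if np.isfinite(r.precision)]
        rows.append(
            {
                "Method": method,
                "Precision": round(float(np.mean(prec)), 2) if prec else np.nan,
                "Sensitivity": round(
                    float(np.mean([r.sensitivity for r in results])), 2
                ),
            }
        )
    return pd.DataFrame(rows)
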