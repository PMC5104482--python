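"""Three-stage filter cascade reducing candidates to strong direct edges.

Stage 1 — data-processing inequality (DPI): for a directed chain
X->Y->Z among current candidates, information between the endpoints
cannot exceed either link, so if PSTE_{X->Z} <= PSTE_{X->Y} and
PSTE_{X->Z} <= PSTE_{Y->Z} the X->Z edge is judged indirect and
removed.  All triples are judged simultaneously against the pre-pass
matrix in a single pass.

Stage 2 — bidirectional dominance: when both directions of a pair are
candidates and one strength times the factor (default 0.4) still meets
or exceeds the other, the weaker direction is removed.

Stage 3 — Granger causality: PSTE measures co-variation of rank
dynamics but not of values; a surviving edge must also pass a pairwise
linear Granger F-test (restricted autoregression of the target vs. the
same model augmented with source lags) at the configured significance
level.

Each stage only removes edges, and every removal records which stage
made it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import RunConfig, TimeSeriesMatrix
from .spectrum import CandidateMatrix

__all__ = [
    "GCResult",
    "StrongEdgeMatrix",
    "dpi_filter",
    "bidirectional_filter",
    "granger_matrix",
    "granger_filter",
    "filter_cascade",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GCResult:
    """Outcome of one pairwise Granger test (source -> target)."""

    pvalue: float
    order: int
    significant: bool


@dataclass(frozen=True)
class StrongEdgeMatrix:
    """Post-filter adjacency plus removal provenance.

    ``provenance`` maps each removed candidate (source index, target
    index) to the stage that removed it: 'dpi', 'bidirectional' or
    'granger'.
    """

    a: np.ndarray
    best_lag: np.ndarray
    names: tuple[str, ...]
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)

    def pairs(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.a == 1)]

    def edge_names(self) -> set[tuple[str, str]]:
        return {(self.names[i], self.names[j]) for i, j in self.pairs()}


def dpi_filter(
    candidates: CandidateMatrix, strengths: np.ndarray
) -> tuple[CandidateMatrix, dict[tuple[int, int], str]]:
    """Single simultaneous DPI pass over directed chains X->Y->Z."""
    a = candidates.a.copy()
    removed: dict[tuple[int, int], str] = {}
    n = candidates.n
    pre = candidates.a  # judge every triple on the pre-pass state
    for x in range(n):
        for y in range(n):
            if x == y or not pre[x, y]:
                continue
            for z in range(n):
                if z in (x, y) or not pre[y, z] or not pre[x, z]:
                    continue
                if (
                    strengths[x, z] <= strengths[x, y]
                    and strengths[x, z] <= strengths[y, z]
                ):
                    if a[x, z]:
                        a[x, z] = 0
                        removed[(x, z)] = "dpi"
    return CandidateMatrix(a=a, best_lag=candidates.best_lag, names=candidates.names), removed


def bidirectional_filter(
    candidates: CandidateMatrix, strengths: np.ndarray, factor: float
) -> tuple[CandidateMatrix, dict[tuple[int, int], str]]:
    """Dominance rule for pairs that are candidates in both directions.

    If s_ij * factor >= s_ji the direction j->i is removed (and
    symmetrically).  Should both conditions hold at once, the stronger
    direction survives; an exact tie keeps both.
    """
    a = candidates.a.copy()
    removed: dict[tuple[int, int], str] = {}
    n = candidates.n
    for i in range(n):
        for j in range(i + 1, n):
            if not (candidates.a[i, j] and candidates.a[j, i]):
                continue
            s_ij, s_ji = strengths[i, j], strengths[j, i]
            drop_ji = s_ij * factor >= s_ji
            drop_ij = s_ji * factor >= s_ij
            if drop_ji and drop_ij:
                if s_ij > s_ji:
                    drop_ij = False
                elif s_ji > s_ij:
                    drop_ji = False
                else:  # exact tie: non-destructive
                    drop_ij = drop_ji = False
            if drop_ji:
                a[j, i] = 0
                removed[(j, i)] = "bidirectional"
            if drop_ij:
                a[i, j] = 0
                removed[(i, j)] = "bidirectional"
    return CandidateMatrix(a=a, best_lag=candidates.best_lag, names=candidates.names), removed


def _lag_design(series: np.ndarray, max_order: int) -> np.ndarray:
    """Columns 0..max_order-1 hold lags 1..max_order, rows aligned to
    t = max_order..k-1."""
    k = series.size
    return np.column_stack(
        [series[max_order - p : k - p] for p in range(1, max_order + 1)]
    )


def granger_pair(
    source: np.ndarray, target: np.ndarray, max_order: int, alpha: float
) -> GCResult:
    """Pairwise linear Granger test with BIC order selection.

    For each order p in 1..max_order the unrestricted model regresses
    the target on a constant, p of its own lags and p source lags; the
    order minimizing the unrestricted BIC is kept and compared with the
    restricted (own-lags-only) model by an F-test on residual sums of
    squares.  All orders are fitted on the common sample t >
    max_order so BIC values are comparable.
    """
    k = target.size
    y = target[max_order:]
    nobs = y.size
    ylags = _lag_design(target, max_order)
    xlags = _lag_design(source, max_order)
    if np.ptp(target) == 0 or np.ptp(source) == 0:
        logger.warning("constant series in Granger test; marking not significant")
        return GCResult(pvalue=1.0, order=0, significant=False)
    const = np.ones((nobs, 1))
    best = None  # (bic, order, rss_u, rss_r, df_num, df_den)
    for p in range(1, max_order + 1):
        Xr = np.hstack([const, ylags[:, :p]])
        Xu = np.hstack([const, ylags[:, :p], xlags[:, :p]])
        rss_r = _rss(Xr, y)
        rss_u = _rss(Xu, y)
        if not np.isfinite(rss_u) or rss_u <= 0:
            continue
        n_par = Xu.shape[1]
        bic = nobs * np.log(rss_u / nobs) + n_par * np.log(nobs)
        df_den = nobs - n_par
        if df_den <= 0:
            continue
        if best is None or bic < best[0]:
            best = (bic, p, rss_u, rss_r, p, df_den)
    if best is None:
        logger.warning("singular Granger regression; marking not significant")
        return GCResult(pvalue=1.0, order=0, significant=False)
    _, order, rss_u, rss_r, df_num, df_den = best
    if rss_u == 0:
        pvalue = 0.0
    else:
        f_stat = ((rss_r - rss_u) / df_num) / (rss_u / df_den)
        pvalue = float(stats.f.sf(max(f_stat, 0.0), df_num, df_den))
    return GCResult(pvalue=pvalue, order=order, significant=pvalue < alpha)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def granger_matrix(
    ts: TimeSeriesMatrix,
    cfg: RunConfig,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], GCResult]:
    """Pairwise Granger tests for the given ordered pairs (all ordered
    pairs by default)."""
    if pairs is None:
        pairs = [
            (i, j) for i in range(ts.n) for j in range(ts.n) if i != j
        ]
    results: dict[tuple[int, int], GCResult] = {}
    for i, j in pairs:
        results[(i, j)] = granger_pair(
            ts.values[:, i], ts.values[:, j], cfg.tm, cfg.gc_alpha
        )
    return results


def granger_filter(
    candidates: CandidateMatrix,
    gc: dict[tuple[int, int], GCResult],
    provenance: dict[tuple[int, int], str] | None = None,
) -> StrongEdgeMatrix:
    """Remove surviving candidates whose Granger test is not significant."""
    a = candidates.a.copy()
    prov = dict(provenance or {})
    for i, j in candidates.pairs():
        res = gc.get((i, j))
        if res is None or not res.significant:
            a[i, j] = 0
            prov[(i, j)] = "granger"
    return StrongEdgeMatrix(
        a=a, best_lag=candidates.best_lag, names=candidates.names, provenance=prov
    )


def filter_cascade(
    candidates: CandidateMatrix,
    strengths: np.ndarray,
    ts: TimeSeriesMatrix,
    cfg: RunConfig,
) -> StrongEdgeMatrix:
    """DPI, then bidirectional dominance, then Granger confirmation."""
    after_dpi, removed_dpi = dpi_filter(candidates, strengths)
    after_bidir, removed_bidir = bidirectional_filter(
        after_dpi, strengths, cfg.bidir_factor
    )
    gc = granger_matrix(ts, cfg, pairs=after_bidir.pairs())
    return granger_filter(after_bidir, gc, {**removed_dpi, **removed_bidir})
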