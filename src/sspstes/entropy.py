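"""Symbolic and partial symbolic transfer entropy, and the full sweep.

Symbolic transfer entropy (STE) from a source X to a target Y at
coupling lag tau is the plug-in estimate of

    STE_{X->Y}(tau) = sum p(y^_{t+1}, y^_t, x^_{t+1-tau})
                      log [ p(y^_{t+1} | y^_t, x^_{t+1-tau})
                            / p(y^_{t+1} | y^_t) ]

over rank-point symbols y^, x^, with all probabilities taken as
relative frequencies: how much the source's symbol tau steps back
improves the one-step prediction of the target's next symbol beyond
the target's own current symbol.  At tau = 1 this is the textbook
symbolic transfer entropy; larger tau lag the *source* window while
the target's conditioning symbol stays adjacent to the predicted one.
Keeping the conditioning adjacent (rather than leaving a tau-wide gap
to the future) makes the statistic comparable across lags — a gap
form systematically under-weights couplings at lags below the
embedding span, because future and conditioning windows then share
samples — so the arg-max over tau estimates the generative coupling
lag.

Partial STE (PSTE) additionally conditions both terms on z^_t, the
concatenated rank-points of every remaining variable, which suppresses
information flow mediated by third variables.  With plug-in
frequencies both quantities reduce exactly to entropy differences,

    PSTE = H(y+, y, z) - H(y, z) - H(y+, y, x, z) + H(y, x, z),

which is how they are computed here: symbols are packed into integers
and each entropy is a counting pass, making the (1+sm) x tm x n x (n-1)
sweep the only heavy loop in the pipeline.

Estimates are raw plug-in values — no small-sample bias correction.
The surrogate comparison downstream absorbs the (shared) bias.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import RunConfig, TimeSeriesMatrix, ValidationError
from .surrogates import SurrogateSet
from .symbolic import RankSeries, pattern_codes, symbolize

__all__ = ["JointFrequencyTable", "PSTETensor", "ste", "pste", "pste_sweep"]


@dataclass(frozen=True)
class JointFrequencyTable:
    """Relative-frequency table over composite symbol keys."""

    counts: Counter
    total: int

    @classmethod
    def from_keys(cls, keys: np.ndarray) -> "JointFrequencyTable":
        return cls(counts=Counter(keys.tolist()), total=int(keys.size))

    def entropy(self) -> float:
        counts = np.array(list(self.counts.values()), dtype=float)
        n = counts.sum()
        return float(np.log(n) - (counts * np.log(counts)).sum() / n)


def _entropy_of_keys(keys: np.ndarray) -> float:
    """Shannon entropy (nats) of the empirical distribution of ``keys``."""
    _, counts = np.unique(keys, return_counts=True)
    n = keys.size
    return float(np.log(n) - (counts * np.log(counts)).sum() / n)


def _te_from_codes(
    y_codes: np.ndarray, x_codes: np.ndarray, z_codes: np.ndarray | None, lag: int
) -> float:
    """PSTE from packed symbol code arrays aligned on a common index.

    Usable time points are those where y_{t+1}, y_t, z_t and
    x_{t+1-lag} all exist, so the sample shrinks by ``lag`` points.
    """
    if lag < 1:
        raise ValidationError("coupling lag must be >= 1")
    if y_codes.size <= lag:
        raise ValidationError(
            f"no usable triples: {y_codes.size} aligned points, lag {lag}"
        )
    yf = y_codes[lag:]
    yp = y_codes[lag - 1 : -1]
    xp = x_codes[:-lag]
    base = int(max(y_codes.max(), x_codes.max())) + 1
    if z_codes is None:
        key_yz = yp.astype(np.int64)
        key_yxz = yp.astype(np.int64) * base + xp
    else:
        zp = z_codes[lag - 1 : -1].astype(np.int64)
        zbase = int(z_codes.max()) + 1
        key_yz = yp * zbase + zp
        key_yxz = (yp.astype(np.int64) * base + xp) * zbase + zp
    key_fyz = yf * (key_yz.max() + 1) + key_yz
    key_fyxz = yf * (key_yxz.max() + 1) + key_yxz
    h_fyz = _entropy_of_keys(key_fyz)
    h_yz = _entropy_of_keys(key_yz)
    h_fyxz = _entropy_of_keys(key_fyxz)
    h_yxz = _entropy_of_keys(key_yxz)
    return (h_fyz - h_yz) - (h_fyxz - h_yxz)


def _check_aligned(*series: RankSeries) -> int:
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValidationError(
            f"rank series must share a common time index; lengths {sorted(lengths)}"
        )
    params = {(s.m, s.tau_embed) for s in series}
    if len(params) != 1:
        raise ValidationError("rank series must share embedding parameters")
    return lengths.pop()


def _pack_conditioning(conditioning: Sequence[RankSeries]) -> np.ndarray | None:
    if not conditioning:
        return None
    z = np.zeros(len(conditioning[0]), dtype=np.int64)
    for rs in conditioning:
        codes = pattern_codes(rs)
        z = z * (rs.m**rs.m) + codes
    # densify so downstream key ranges stay small
    _, dense = np.unique(z, return_inverse=True)
    return dense


def ste(target_ranks: RankSeries, source_ranks: RankSeries, lag: int) -> float:
    """Symbolic transfer entropy source -> target at coupling lag
    ``lag`` (nats)."""
    return pste(target_ranks, source_ranks, (), lag)


def pste(
    target_ranks: RankSeries,
    source_ranks: RankSeries,
    conditioning: Sequence[RankSeries],
    lag: int,
) -> float:
    """Partial symbolic transfer entropy source -> target given the
    conditioning set (nats).  Empty conditioning reduces exactly to
    :func:`ste`."""
    _check_aligned(target_ranks, source_ranks, *conditioning)
    y = pattern_codes(target_ranks)
    x = pattern_codes(source_ranks)
    z = _pack_conditioning(conditioning)
    return _te_from_codes(y, x, z, lag)


@dataclass(frozen=True)
class PSTETensor:
    """PSTE values over (dataset, lag, source, target).

    ``values[d, t-1, i, j]`` is PSTE_{i->j} at coupling lag t on
    dataset d (0 = original, 1..sm = surrogates), conditioned on all
    remaining variables.  The diagonal is NaN — autocorrelation is
    never evaluated.  Plug-in values can be slightly negative; no
    clipping is applied.
    """

    values: np.ndarray  # (1+sm, tm, n, n)
    names: tuple[str, ...]
    unit: str = "nats"

    @property
    def n_datasets(self) -> int:
        return self.values.shape[0]

    @property
    def tm(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[2]

    def original_strengths(self) -> np.ndarray:
        """Max over lags of the original-data values, per ordered pair
        (NaN on the diagonal)."""
        vals = np.where(np.isnan(self.values[0]), -np.inf, self.values[0])
        out = np.max(vals, axis=0)
        return np.where(np.isinf(out), np.nan, out)


def _dataset_codes(ts: TimeSeriesMatrix, cfg: RunConfig) -> np.ndarray:
    """Symbolize every column of one dataset and pack to dense integer
    codes (k' x n).  Symbolization happens once per dataset and is
    reused across lags and pairs."""
    cols = [
        pattern_codes(symbolize(ts.values[:, c], cfg.m, cfg.tau_embed))
        for c in range(ts.n)
    ]
    codes = np.column_stack(cols)
    _, dense = np.unique(codes, return_inverse=True)
    return dense.reshape(codes.shape).astype(np.int64)


def _sweep_one(codes: np.ndarray, cfg: RunConfig) -> np.ndarray:
    """PSTE for every ordered pair and lag 1..tm on one dataset."""
    kprime, n = codes.shape
    if kprime <= cfg.tm:
        raise ValidationError(
            f"series too short: {kprime} symbolized points for tm={cfg.tm}"
        )
    nsym = int(codes.max()) + 1
    out = np.full((cfg.tm, n, n), np.nan)
    # conditioning packs depend only on the unordered pair
    for i in range(n):
        for j in range(i + 1, n):
            others = [c for c in range(n) if c not in (i, j)]
            if others:
                z = np.zeros(kprime, dtype=np.int64)
                for c in others:
                    z = z * nsym + codes[:, c]
                _, z = np.unique(z, return_inverse=True)
                z = z.astype(np.int64)
                nz = int(z.max()) + 1
            else:
                z = None
                nz = 1
            for src, tgt in ((i, j), (j, i)):
                y = codes[:, tgt]
                x = codes[:, src]
                for lag in range(1, cfg.tm + 1):
                    yf = y[lag:]
                    yp = y[lag - 1 : -1]
                    xp = x[:-lag]
                    if z is not None:
                        zp = z[lag - 1 : -1]
                        key_yz = yp * nz + zp
                        key_yxz = (yp * nsym + xp) * nz + zp
                    else:
                        key_yz = yp
                        key_yxz = yp * nsym + xp
                    span_yz = nsym * nz
                    span_yxz = nsym * nsym * nz
                    h_fyz = _entropy_of_keys(yf * span_yz + key_yz)
                    h_yz = _entropy_of_keys(key_yz)
                    h_fyxz = _entropy_of_keys(yf * span_yxz + key_yxz)
                    h_yxz = _entropy_of_keys(key_yxz)
                    out[lag - 1, src, tgt] = (h_fyz - h_yz) - (h_fyxz - h_yxz)
    return out


def pste_sweep(
    data: TimeSeriesMatrix | SurrogateSet,
    cfg: RunConfig,
    *,
    condition: bool | None = None,
) -> PSTETensor:
    """Run the full PSTE sweep: every dataset (original + surrogates),
    every prediction lag 1..tm, every ordered pair, conditioned on all
    remaining variables.

    Passing a bare :class:`TimeSeriesMatrix` sweeps that single dataset
    (dataset axis of length 1).  ``condition`` overrides
    ``cfg.conditioning``: True conditions every pair on all remaining
    variables (the partial statistic), False yields the plain pairwise
    STE sweep.
    """
    if condition is None:
        condition = cfg.conditioning == "full"
    if isinstance(data, SurrogateSet):
        datasets = list(data.datasets())
    else:
        datasets = [data]
    names = datasets[0].names
    n = len(names)
    if n < 2:
        raise ValidationError("need at least 2 variables")
    sweep_cfg = cfg
    slabs = []
    for ts in datasets:
        codes = _dataset_codes(ts, sweep_cfg)
        if not condition and n > 2:
            # restrict each pair to its own two columns: run the kernel
            # pairwise with an empty conditioning set
            kprime = codes.shape[0]
            slab = np.full((cfg.tm, n, n), np.nan)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    sub = _sweep_one(codes[:, [i, j]], cfg)
                    slab[:, i, j] = sub[:, 0, 1]
            slabs.append(slab)
        else:
            slabs.append(_sweep_one(codes, cfg))
    return PSTETensor(values=np.stack(slabs), names=names)
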