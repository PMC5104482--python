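"""Delay embedding and rank (ordinal-pattern) symbolization.

Each scalar series is delay-embedded into m-vectors
(v_t, v_{t-tau}, ..., v_{t-(m-1)tau}) and each vector is replaced by the
ascending ranks of its components — its ordinal pattern.  The alphabet
has m! symbols.  Ranks are invariant under any strictly increasing
transform of the data, which is what makes the downstream transfer
entropies robust to slow drifts and monotone distortions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

__all__ = ["RankSeries", "embed", "rank_point", "symbolize", "pattern_codes"]


@dataclass(frozen=True)
class RankSeries:
    """Sequence of rank-points of one embedded series.

    ``ranks`` has one row per valid time point; row t holds the ranks
    (1..m) of (v_t, v_{t-tau}, ..., v_{t-(m-1)tau}), current value first.
    ``offset`` is the number of leading time points consumed by the
    embedding, i.e. (m-1)*tau.
    """

    ranks: np.ndarray
    m: int
    tau_embed: int

    @property
    def offset(self) -> int:
        return (self.m - 1) * self.tau_embed

    def __len__(self) -> int:
        return self.ranks.shape[0]


def embed(series: np.ndarray, m: int, tau_embed: int = 1) -> np.ndarray:
    """Delay-embed a scalar series; row t is (v_t, v_{t-tau}, ...,
    v_{t-(m-1)tau}), first valid t being (m-1)*tau (0-based)."""
    series = np.asarray(series, dtype=float)
    if m < 1 or tau_embed < 1:
        raise ValidationError("m and tau_embed must be >= 1")
    window = (m - 1) * tau_embed + 1
    if series.size < window:
        raise ValidationError(
            f"series of length {series.size} too short for m={m}, "
            f"tau={tau_embed}; need at least {window} points"
        )
    strided = np.lib.stride_tricks.sliding_window_view(series, window)
    idx = window - 1 - tau_embed * np.arange(m)
    return strided[:, idx]


def rank_point(vector: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..m of a vector's components; ties break by
    position (the earlier component takes the smaller rank)."""
    vector = np.asarray(vector, dtype=float)
    order = np.argsort(vector, kind="stable")
    ranks = np.empty(vector.size, dtype=np.int64)
    ranks[order] = np.arange(1, vector.size + 1)
    return ranks


def symbolize(series: np.ndarray, m: int, tau_embed: int = 1) -> RankSeries:
    """Embed then rank every row: the rank-point series of one variable."""
    vectors = embed(series, m, tau_embed)
    order = np.argsort(vectors, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(vectors.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, m + 1)
    return RankSeries(ranks=ranks, m=m, tau_embed=tau_embed)


def pattern_codes(rs: RankSeries) -> np.ndarray:
    """Encode each rank-point as one integer in [0, m**m) by mixed-radix
    packing; distinct patterns map to distinct codes."""
    weights = rs.m ** np.arange(rs.m, dtype=np.int64)
    return (rs.ranks - 1) @ weights
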