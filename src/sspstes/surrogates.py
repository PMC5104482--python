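"""Small-shuffle surrogate (SSS) generation.

A small-shuffle surrogate perturbs the *time indices* of a series with
Gaussian noise of amplitude A and re-sorts them: i'(t) = t + A*g(t),
g(t) ~ N(0,1) i.i.d.  Evaluating the series at the rank order of i'
yields a permutation of the original values that destroys short-term
correlation structure while preserving any slow global trend.  Under
the null hypothesis that the irregular fluctuations of two series are
independent, transfer entropy computed on surrogates forms the
reference distribution against which the original is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RunConfig, TimeSeriesMatrix, ValidationError

__all__ = ["SurrogateSet", "small_shuffle", "make_surrogate_set"]

# Fixed stream label so surrogate draws never collide with simulation draws
# derived from the same master seed.
_SURROGATE_STREAM = 0x5355


@dataclass(frozen=True)
class SurrogateSet:
    """An original series plus its family of small-shuffle surrogates."""

    original: TimeSeriesMatrix
    shuffles: tuple[TimeSeriesMatrix, ...]
    amplitude_A: float
    seed: int

    @property
    def sm(self) -> int:
        return len(self.shuffles)

    def datasets(self):
        """Original first, then each surrogate — the sweep order."""
        yield self.original
        yield from self.shuffles


def small_shuffle(
    series: np.ndarray, amplitude_A: float, rng: np.random.Generator
) -> np.ndarray:
    """Return one small-shuffle surrogate of a scalar series.

    With A = 0 the perturbed indices are already sorted and the output
    equals the input; for any A the output is a permutation of the
    input, so every marginal moment is preserved exactly.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValidationError("series must be 1-D with length >= 2")
    if amplitude_A < 0:
        raise ValidationError("amplitude_A must be >= 0")
    t = np.arange(series.size, dtype=float)
    perturbed = t + amplitude_A * rng.standard_normal(series.size)
    # stable sort: ties among perturbed indices break by original position
    order = np.argsort(perturbed, kind="stable")
    return series[order]


def make_surrogate_set(ts: TimeSeriesMatrix, cfg: RunConfig) -> SurrogateSet:
    """Generate ``cfg.sm`` surrogate matrices, shuffling each column
    independently.

    Every (replicate, column) pair consumes its own RNG substream
    derived from ``cfg.seed``, so increasing ``sm`` extends the set
    without changing earlier surrogates.
    """
    shuffles = []
    for s in range(cfg.sm):
        cols = np.empty_like(ts.values)
        for c in range(ts.n):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(_SURROGATE_STREAM, s, c))
            )
            cols[:, c] = small_shuffle(ts.values[:, c], cfg.amplitude_A, rng)
        shuffles.append(TimeSeriesMatrix(values=cols, names=ts.names))
    return SurrogateSet(
        original=ts,
        shuffles=tuple(shuffles),
        amplitude_A=cfg.amplitude_A,
        seed=cfg.seed,
    )
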