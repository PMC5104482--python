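"""Transfer-entropy spectra and the surrogate outlier test.

For one ordered pair of variables the spectrum is the original-data
PSTE curve over coupling lags 1..tm overlaid on the family of sm
surrogate curves.  A directed relationship is a *candidate* when the
original curve rises, at some lag, strictly above the global maximum of
the whole surrogate family — the one-sided surrogate hypothesis test
with the strictest (all surrogates, all lags) envelope.  The lag
assigned to a candidate is the arg-max of its original curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .entropy import PSTETensor

__all__ = ["Spectrum", "CandidateMatrix", "build_spectra", "identify_candidates", "plot_spectrum"]


@dataclass(frozen=True)
class Spectrum:
    """Original + surrogate PSTE curves for one ordered pair."""

    source: str
    target: str
    original_curve: np.ndarray  # (tm,)
    surrogate_curves: np.ndarray  # (sm, tm)
    display_scale: float = 100.0

    @property
    def tm(self) -> int:
        return self.original_curve.size

    @property
    def sm(self) -> int:
        return self.surrogate_curves.shape[0]

    @property
    def best_lag(self) -> int:
        """Arg-max lag of the original curve (1-based, ties toward the
        smaller lag)."""
        return int(np.argmax(self.original_curve)) + 1

    def is_candidate(self) -> bool:
        """Strict surrogate outlier test: some original value exceeds
        every surrogate value at every lag."""
        envelope = float(self.surrogate_curves.max())
        return bool(self.original_curve.max() > envelope)


@dataclass(frozen=True)
class CandidateMatrix:
    """Binary adjacency of candidate relationships with their lags."""

    a: np.ndarray  # (n, n) of {0,1}, zero diagonal
    best_lag: np.ndarray  # (n, n) int, valid where a == 1
    names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def pairs(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.a == 1)]

    def edge_names(self) -> set[tuple[str, str]]:
        return {(self.names[i], self.names[j]) for i, j in self.pairs()}


def build_spectra(tensor: PSTETensor) -> dict[tuple[str, str], Spectrum]:
    """Split the sweep tensor into one spectrum per ordered pair."""
    spectra: dict[tuple[str, str], Spectrum] = {}
    for i, src in enumerate(tensor.names):
        for j, tgt in enumerate(tensor.names):
            if i == j:
                continue
            spectra[(src, tgt)] = Spectrum(
                source=src,
                target=tgt,
                original_curve=tensor.values[0, :, i, j].copy(),
                surrogate_curves=tensor.values[1:, :, i, j].copy(),
            )
    return spectra


def identify_candidates(
    spectra: dict[tuple[str, str], Spectrum]
) -> CandidateMatrix:
    """Apply the surrogate outlier test to every spectrum."""
    # node order = first appearance in the spectra mapping
    ordered: list[str] = []
    for s, t in spectra:
        for v in (s, t):
            if v not in ordered:
                ordered.append(v)
    names = ordered
    n = len(names)
    idx = {v: i for i, v in enumerate(names)}
    a = np.zeros((n, n), dtype=int)
    best_lag = np.zeros((n, n), dtype=int)
    for (src, tgt), spec in spectra.items():
        i, j = idx[src], idx[tgt]
        if spec.is_candidate():
            a[i, j] = 1
            best_lag[i, j] = spec.best_lag
    return CandidateMatrix(a=a, best_lag=best_lag, names=tuple(names))


def plot_spectrum(s: Spectrum, path: str | Path) -> None:
    """Plot one spectrum: lags on x, PSTE x display_scale on y, the
    original curve highlighted over the surrogate family."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lags = np.arange(1, s.tm + 1)
    fig, ax = plt.subplots(figsize=(4, 3))
    for curve in s.surrogate_curves:
        ax.plot(lags, curve * s.display_scale, color="0.6", lw=0.6, zorder=1)
    ax.plot(
        lags,
        s.original_curve * s.display_scale,
        color="crimson",
        lw=1.8,
        zorder=2,
        label="original",
    )
    ax.set_xlabel("coupling lag")
    ax.set_ylabel(f"PSTE × {s.display_scale:g}")
    ax.set_title(f"{s.source} → {s.target}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
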