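import math
from collections import Counter

import numpy as np
import pytest

from sspstes import RunConfig, TimeSeriesMatrix, ValidationError, pste, pste_sweep, ste
from sspstes import make_surrogate_set
from sspstes.symbolic import symbolize


def naive_pste(target, source, conditioning, m, lag):
    """Literal term-by-term plug-in estimate of the partial symbolic
    transfer entropy: materialize every joint tuple of rank-points and
    sum p * log(p(y+|y,x,z) / p(y+|y,z)), with the target/conditioning
    symbols adjacent to the predicted one and the source symbol lagged
    by ``lag``.  Independent of the packed fast path in the library."""

    def sym(series):
        out = []
        for t in range(m - 1, len(series)):
            vec = [series[t - i] for i in range(m)]
            order = sorted(range(m), key=lambda i: (vec[i], i))
            ranks = [0] * m
            for r, i in enumerate(order):
                ranks[i] = r + 1
            out.append(tuple(ranks))
        return out

    ys, xs = sym(target), sym(source)
    zs = [sym(c) for c in conditioning]
    tuples = []
    for t in range(len(ys) - lag):
        z = tuple(zc[t + lag - 1] for zc in zs)
        tuples.append((ys[t + lag], ys[t + lag - 1], xs[t], z))
    n = len(tuples)
    c_full = Counter(tuples)
    c_yxz = Counter((y, x, z) for _, y, x, z in tuples)
    c_fyz = Counter((f, y, z) for f, y, _, z in tuples)
    c_yz = Counter((y, z) for _, y, _, z in tuples)
    total = 0.0
    for (f, y, x, z), cnt in c_full.items():
        p = cnt / n
        p_f_yxz = cnt / c_yxz[(y, x, z)]
        p_f_yz = c_fyz[(f, y, z)] / c_yz[(y, z)]
        total += p * math.log(p_f_yxz / p_f_yz)
    return total


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_cond", [0, 1, 2])
    @pytest.mark.parametrize("lag", [1, 3])
    def test_matches_naive_enumeration(self, rng, n_cond, lag):
        """Fast packed-key estimator agrees with the literal formula to
        1e-12 at m=2, k<=200."""
        k, m = 200, 2
        target = rng.standard_normal(k)
        source = rng.standard_normal(k)
        conds = [rng.standard_normal(k) for _ in range(n_cond)]
        expected = naive_pste(target, source, conds, m, lag)
        got = pste(
            symbolize(target, m),
            symbolize(source, m),
            [symbolize(c, m) for c in conds],
            lag,
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_m3_against_naive(self, rng):
        k = 150
        target, source, cond = (rng.standard_normal(k) for _ in range(3))
        expected = naive_pste(target, source, [cond], 3, 2)
        got = pste(symbolize(target, 3), symbolize(source, 3), [symbolize(cond, 3)], 2)
        assert got == pytest.approx(expected, abs=1e-12)


class TestSteProperties:
    def test_empty_conditioning_reduces_to_ste(self, rng):
        x, y = rng.standard_normal(300), rng.standard_normal(300)
        sx, sy = symbolize(x, 3), symbolize(y, 3)
        assert pste(sy, sx, [], 2) == ste(sy, sx, 2)

    def test_independent_series_near_zero(self, rng):
        """Finite-sample bias only: i.i.d. source and target, m=2,
        k=1000."""
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        val = ste(symbolize(y, 2), symbolize(x, 2), 1)
        assert 0 <= val < 0.01

    def test_deterministic_coupling_strong_and_asymmetric(self, rng):
        """y(t+1) = x(t): the source's rank fully determines the
        target's next move."""
        x = rng.standard_normal(1000)
        y = np.roll(x, 1)
        sx, sy = symbolize(x, 2), symbolize(y, 2)
        forward = ste(sy, sx, 1)
        backward = ste(sx, sy, 1)
        assert forward > 0.5
        assert forward > 10 * backward

    def test_constant_target_gives_zero(self, rng):
        y = np.zeros(200)
        x = rng.standard_normal(200)
        assert ste(symbolize(y, 2), symbolize(x, 2), 1) == 0.0

    def test_conditioning_removes_mediated_flow(self):
        """Chain x -> y -> z: conditioning on the mediator y lowers the
        apparent x -> z transfer in most replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 800
            x = rng.standard_normal(n)
            y = np.roll(x, 1) + 0.3 * rng.standard_normal(n)
            z = np.roll(y, 1) + 0.3 * rng.standard_normal(n)
            sx, sy, sz = (symbolize(v, 2) for v in (x, y, z))
            if pste(sz, sx, [sy], 2) < ste(sz, sx, 2):
                wins += 1
        assert wins >= 16

    def test_irrelevant_conditioning_small_shift(self):
        """Conditioning on an independent series moves the estimate by
        less than the replicate-to-replicate noise of STE itself."""
        diffs, stes = [], []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(600)
            y = np.roll(x, 1) + 0.5 * rng.standard_normal(600)
            w = rng.standard_normal(600)
            sx, sy, sw = (symbolize(v, 2) for v in (x, y, w))
            s = ste(sy, sx, 1)
            stes.append(s)
            diffs.append(abs(pste(sy, sx, [sw], 1) - s))
        assert np.mean(diffs) < 3 * np.std(stes) + 0.01

    def test_no_usable_triples_raises(self, rng):
        s = symbolize(rng.standard_normal(5), 2)
        with pytest.raises(ValidationError):
            ste(s, s, 10)


class TestPsteSweep:
    def test_n2_equals_ste_sweep(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((200, 2)), ("a", "b"))
        cfg = RunConfig(sm=1, tm=4, seed=0, conditioning="full")
        full = pste_sweep(ts, cfg)
        pairwise = pste_sweep(ts, cfg, condition=False)
        np.testing.assert_array_equal(full.values, pairwise.values)

    def test_tensor_shape_and_diagonal(self, tiny_ts):
        cfg = RunConfig(sm=2, tm=3, seed=0)
        tensor = pste_sweep(make_surrogate_set(tiny_ts, cfg), cfg)
        assert tensor.values.shape == (3, 3, 3, 3)
        assert np.all(np.isnan(tensor.values[:, :, np.arange(3), np.arange(3)]))
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.isfinite(tensor.values[:, :, off]))

    def test_sweep_matches_single_pair_calls(self, rng):
        """Tensor entries equal individual pste() calls on the same
        symbolized columns."""
        ts = TimeSeriesMatrix(rng.standard_normal((150, 3)), ("a", "b", "c"))
        cfg = RunConfig(sm=1, tm=3, seed=0, conditioning="full")
        tensor = pste_sweep(ts, cfg)
        syms = [symbolize(ts.values[:, c], cfg.m) for c in range(3)]
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                conds = [syms[c] for c in range(3) if c not in (i, j)]
                for lag in (1, 3):
                    expected = pste(syms[j], syms[i], conds, lag)
                    assert tensor.values[0, lag - 1, i, j] == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_determinism(self, tiny_ts):
        cfg = RunConfig(sm=3, tm=3, seed=5)
        a = pste_sweep(make_surrogate_set(tiny_ts, cfg), cfg)
        b = pste_sweep(make_surrogate_set(tiny_ts, cfg), cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_surrogates_destroy_coupling(self, rng):
        """For a strongly coupled pair the original statistic at the
        true lag exceeds the surrogate values at that lag in the vast
        majority of surrogates."""
        n = 600
        x = rng.standard_normal(n)
        y = np.roll(x, 2) + 0.4 * rng.standard_normal(n)
        ts = TimeSeriesMatrix(np.column_stack([x, y]), ("x", "y"))
        cfg = RunConfig(sm=19, tm=4, seed=3)
        tensor = pste_sweep(make_surrogate_set(ts, cfg), cfg)
        orig = tensor.values[0, 1, 0, 1]  # lag 2, x->y
        surr = tensor.values[1:, 1, 0, 1]
        assert np.mean(orig > surr) >= 0.95
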