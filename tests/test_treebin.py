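import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandtree import (
    PowerSpectrum,
    best_split,
    dp_optimal_partition,
    dp_sse_curve,
    grow_nested,
    grow_partition,
    r_squared,
)


def seg_sse(y):
    y = np.asarray(y, float)
    return float(((y - y.mean()) ** 2).sum())


def brute_force_best_split(y):
    """Enumerate every cut point; ties to the smallest index."""
    best = None
    for i in range(1, len(y)):
        s = seg_sse(y[:i]) + seg_sse(y[i:])
        if best is None or s < best[1] - 1e-12:
            best = (i, s)
    return best[0], seg_sse(y) - best[1]


def brute_force_optimal_sse(y, k):
    """Minimal SSE over all placements of k-1 cuts (combinatorial oracle)."""
    n = len(y)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        sse = sum(seg_sse(y[a:b]) for a, b in zip(edges[:-1], edges[1:]))
        best = min(best, sse)
    return best


class TestBestSplit:
    def test_two_level_step(self):
        idx, dec = best_split([0, 0, 0, 5, 5])
        assert idx == 3
        assert dec == pytest.approx(30.0)  # SSE 30 -> 0

    def test_constant_ties_break_to_first_cut(self):
        idx, dec = best_split(np.full(6, 2.0))
        assert idx == 1
        assert dec == pytest.approx(0.0)

    def test_unsplittable(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            best_split([1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=rng.integers(2, 13))
        idx, dec = best_split(y)
        bidx, bdec = brute_force_best_split(y)
        assert idx == bidx
        assert dec == pytest.approx(bdec, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12))
    def test_split_never_increases_sse(self, y):
        idx, dec = best_split(y)
        assert 1 <= idx < len(y)
        assert dec >= 0


class TestGrowPartition:
    def test_single_band_is_null_model(self, make_random_spectrum):
        s = make_random_spectrum(1)
        p = grow_partition(s, 1)
        assert p.boundaries.size == 0
        assert p.band_means[0] == pytest.approx(np.log(s.psd).mean())
        assert p.r2 == pytest.approx(0.0)

    def test_saturated_model(self, make_random_spectrum):
        s = make_random_spectrum(2, n=12)
        p = grow_partition(s, s.n)
        assert p.sse == pytest.approx(0.0, abs=1e-12)
        assert p.r2 == pytest.approx(1.0)

    def test_k2_greedy_is_globally_optimal(self, make_random_spectrum):
        for seed in range(10):
            s = make_random_spectrum(seed, n=25)
            assert grow_partition(s, 2).sse == pytest.approx(
                dp_optimal_partition(s, 2).sse, rel=1e-12
            )

    def test_boundary_is_midpoint_of_flanking_samples(self, step_spectrum):
        p = grow_partition(step_spectrum, 2)
        # log target steps between 10 and 11 Hz -> boundary at 10.5
        assert p.boundaries[0] == pytest.approx(10.5)
        assert p.r2 == pytest.approx(1.0)

    def test_invalid_k(self, make_random_spectrum):
        s = make_random_spectrum(3, n=8)
        with pytest.raises(ValueError):
            grow_partition(s, 0)
        with pytest.raises(ValueError):
            grow_partition(s, 9)

    def test_matches_sklearn_best_first_tree(self, make_random_spectrum):
        """A leaf-capped best-first regression tree from an independent
        implementation must produce the identical piecewise-constant fit."""
        DecisionTreeRegressor = pytest.importorskip(
            "sklearn.tree"
        ).DecisionTreeRegressor
        for seed in range(5):
            s = make_random_spectrum(seed, n=40)
            X = s.frequencies.reshape(-1, 1)
            y = np.log(s.psd)
            for k in (2, 4, 7, 13):
                p = grow_partition(s, k)
                tree = DecisionTreeRegressor(max_leaf_nodes=k, random_state=0).fit(X, y)
                assert np.allclose(p.predict(s.frequencies), tree.predict(X), atol=1e-10)


class TestGrowNested:
    @pytest.mark.parametrize("seed", range(8))
    def test_boundaries_nest_and_fit_improves(self, make_random_spectrum, seed):
        s = make_random_spectrum(seed, n=30)
        parts = grow_nested(s, s.n)
        for a, b in zip(parts[:-1], parts[1:]):
            assert set(np.round(a.boundaries, 12)) <= set(np.round(b.boundaries, 12))
            assert b.r2 >= a.r2 - 1e-12
            assert b.sse <= a.sse + 1e-12

    def test_last_element_equals_direct_growth(self, make_random_spectrum):
        s = make_random_spectrum(11, n=20)
        parts = grow_nested(s, 7)
        direct = grow_partition(s, 7)
        assert np.array_equal(parts[-1].boundaries, direct.boundaries)
        assert parts[-1].sse == direct.sse

    def test_every_band_nonempty(self, make_random_spectrum):
        s = make_random_spectrum(5, n=15)
        for p in grow_nested(s, s.n):
            counts = np.bincount(p.assign(s.frequencies), minlength=p.k)
            assert np.all(counts >= 1)


class TestDpOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_dp_never_worse_than_greedy(self, make_random_spectrum, seed):
        s = make_random_spectrum(seed, n=18)
        greedy = grow_nested(s, s.n)
        dp_sse = dp_sse_curve(s)
        for p, opt in zip(greedy, dp_sse):
            assert opt <= p.sse + 1e-9
        # greedy is exact at k = 1, 2, N
        for k in (1, 2, s.n):
            assert greedy[k - 1].sse == pytest.approx(dp_sse[k - 1], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_dp_agrees_with_brute_force(self, make_random_spectrum, seed):
        s = make_random_spectrum(seed, n=9)
        y = np.log(s.psd)
        for k in range(1, s.n + 1):
            dp = dp_optimal_partition(s, k)
            assert dp.sse == pytest.approx(brute_force_optimal_sse(y, k), abs=1e-9)

    def test_saturated_dp_sse_zero(self, make_random_spectrum):
        s = make_random_spectrum(9, n=7)
        assert dp_optimal_partition(s, s.n).sse == pytest.approx(0.0, abs=1e-12)


class TestPartitionContract:
    def test_reconstruction_from_band_means(self, make_random_spectrum):
        s = make_random_spectrum(13, n=40)
        for k in (1, 3, 9, 40):
            p = grow_partition(s, k)
            resid = np.log(s.psd) - p.predict(s.frequencies)
            assert float((resid**2).sum()) == pytest.approx(p.sse, rel=1e-9, abs=1e-12)

    def test_permuting_psd_within_band_preserves_sse(self, make_random_spectrum):
        s = make_random_spectrum(17, n=24)
        p = grow_partition(s, 4)
        idx = p.assign(s.frequencies)
        rng = np.random.default_rng(0)
        psd = s.psd.copy()
        for band in range(4):
            where = np.flatnonzero(idx == band)
            psd[where] = psd[rng.permutation(where)]
        shuffled = PowerSpectrum(s.frequencies, psd)
        assert r_squared(p, shuffled) == pytest.approx(p.r2, rel=1e-12)

    def test_r_squared_conventions(self, make_random_spectrum, step_spectrum):
        s = make_random_spectrum(19, n=16)
        assert r_squared(grow_partition(s, s.n), s) == pytest.approx(1.0)
        assert r_squared(grow_partition(s, 1), s) == pytest.approx(0.0)
        assert r_squared(grow_partition(step_spectrum, 2), step_spectrum) == pytest.approx(1.0)
        flat = PowerSpectrum(np.arange(1.0, 9.0), np.full(8, 2.0))
        assert r_squared(grow_partition(flat, 3), flat) == 0.0

    def test_linear_target(self):
        f = np.arange(1.0, 7.0)
        psd = np.array([4.0, 4.0, 4.0, 1.0, 1.0, 1.0])
        s = PowerSpectrum(f, psd)
        p = grow_partition(s, 2, target="linear")
        assert p.boundaries[0] == pytest.approx(3.5)
        assert np.allclose(p.band_means, [4.0, 1.0])
        assert p.r2 == pytest.approx(1.0)

    def test_json_round_trip(self, make_random_spectrum):
        s = make_random_spectrum(23, n=14)
        p = grow_partition(s, 5)
        d = json.loads(json.dumps(p.to_dict()))
        assert d["k"] == 5
        assert len(d["boundaries_hz"]) == 4
        assert len(d["band_means"]) == 5
        assert d["r2"] == pytest.approx(p.r2)
        assert d["target"] == "log"
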