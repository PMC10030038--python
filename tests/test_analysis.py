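"""Change-point detection, probability estimation, ensemble statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from habitsim import (ChangePointResult, SelectionProbabilitySeries,
                      compare_groups, detect_changepoint,
                      estimate_selection_probabilities, loglik_ratio_series,
                      steady_state_performance)


def brute_force_y(p1, h):
    """Direct, unvectorized evaluation of the printed recursion."""
    y = []
    prev = 0.0
    for p in p1:
        val = math.log(p / (1 - p)) + math.log(
            ((1 - h) * math.exp(prev) + h) / (h * math.exp(prev) + (1 - h)))
        y.append(val)
        prev = val
    return np.array(y)


def brute_force_u(a, b):
    """U as the pair count #(a > b) + 0.5 #(a == b)."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x, y in itertools.product(a, b))


def series(p1, n_reps=1000):
    return SelectionProbabilitySeries(np.asarray(p1, dtype=float), n_reps)


class TestLogLikRatio:
    def test_unbiased_series_stays_at_zero(self):
        r = loglik_ratio_series(series([0.5] * 20), 1 / 201)
        np.testing.assert_allclose(r.y, 0.0, atol=1e-14)
        assert r.changepoint_trial == 1  # y <= 0 immediately

    def test_first_value_is_plain_log_ratio(self):
        r = loglik_ratio_series(series([0.9] * 5), 1 / 201)
        assert r.y[0] == pytest.approx(math.log(9.0), rel=1e-12)
        assert np.all(np.diff(r.y) > 0)  # consistent evidence accumulates

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p1 = rng.uniform(0.01, 0.99, size=50)
            h = rng.uniform(0.001, 0.2)
            r = loglik_ratio_series(series(p1), h)
            np.testing.assert_allclose(r.y, brute_force_y(p1, h),
                                       rtol=1e-10, atol=1e-10)

    def test_stable_for_extreme_series(self):
        # saturating evidence drives |y| to the hundreds without overflow
        p1 = np.concatenate([np.full(300, 0.999), np.full(300, 0.001)])
        r = loglik_ratio_series(series(p1), 1 / 201)
        assert np.all(np.isfinite(r.y))
        assert r.changepoint_trial is not None

    def test_changepoint_follows_preference_switch(self):
        # y saturates near log((1-h)/h) + log(9) ~ 7.4 before the switch,
        # then sheds ~2.2 per trial: the brute-force recursion crosses zero
        # on the third post-switch trial
        p1 = np.array([0.9] * 10 + [0.1] * 10)
        r = loglik_ratio_series(series(p1), 1 / 201)
        assert r.changepoint_trial == 13
        assert r.changepoint_trial == 1 + int(
            np.nonzero(brute_force_y(p1, 1 / 201) <= 0)[0][0])

    def test_rejects_degenerate_probabilities(self):
        with pytest.raises(ValueError):
            series([1.0, 0.5])
        with pytest.raises(ValueError):
            loglik_ratio_series(series([0.5]), hazard=1.5)

    @given(st.integers(0, 2**32 - 1))
    def test_larger_p1_never_crosses_earlier(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.05, 0.9, size=40)
        hi = np.minimum(base + 0.05, 0.95)
        cp_base = loglik_ratio_series(series(base), 1 / 201).changepoint_trial
        cp_hi = loglik_ratio_series(series(hi), 1 / 201).changepoint_trial
        if cp_hi is not None and cp_base is not None:
            assert cp_hi >= cp_base
        elif cp_hi is None:
            pass  # dominating series may simply never cross
        else:
            pytest.fail("dominated series crossed later than dominating one")


class TestDetectChangepoint:
    def test_all_positive_series_has_none(self):
        r = ChangePointResult(np.ones(5), 1 / 201, None)
        assert detect_changepoint(r) is None

    def test_immediate_crossing(self):
        r = ChangePointResult(np.array([-0.2, 1.0]), 1 / 201, None)
        assert detect_changepoint(r) == 1

    def test_symmetric_orientation(self):
        r = ChangePointResult(np.array([-1.0, -2.0, 0.5]), 1 / 201, None)
        # default orientation assumes a start toward channel 1: fires at once
        assert detect_changepoint(r) == 1
        # symmetric orientation keys off the initial sign instead
        assert detect_changepoint(r, orientation="symmetric") == 3


class TestSteadyState:
    def test_projection_of_final_trial(self):
        assert steady_state_performance(series([0.5, 0.97])) == 0.97

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            steady_state_performance(series([]))


class TestEstimateSelectionProbabilities:
    def test_laplace_smoothing_arithmetic(self, fast_params,
                                          trained_weights):
        est = estimate_selection_probabilities(
            trained_weights.as_vector()[None, :], fast_params, n_reps=2,
            seed=0)
        # with 2 reps the only reachable values are {1/4, 2/4, 3/4}
        assert est.action.p1[0] in (0.25, 0.5, 0.75)

    def test_symmetric_weights_near_half(self, fast_params,
                                         symmetric_weights):
        est = estimate_selection_probabilities(
            symmetric_weights.as_vector()[None, :], fast_params,
            n_reps=400, seed=1)
        assert est.action.p1[0] == pytest.approx(0.5, abs=0.1)
        assert est.outcome.p1[0] == pytest.approx(0.5, abs=0.1)

    def test_trained_weights_prefer_channel_one(self, fast_params,
                                                trained_weights):
        est = estimate_selection_probabilities(
            trained_weights.as_vector()[None, :], fast_params,
            n_reps=200, seed=2)
        assert est.action.p1[0] > 0.9
        assert est.outcome.p1[0] > 0.9

    def test_precision_grows_with_reps(self, fast_params, trained_weights):
        # repeated estimates at higher n_reps scatter less (SE ~ 1/sqrt(n))
        w = trained_weights.as_vector()[None, :].repeat(6, axis=0)
        lo = estimate_selection_probabilities(w, fast_params, n_reps=25,
                                              seed=3)
        hi = estimate_selection_probabilities(w, fast_params, n_reps=400,
                                              seed=4)
        assert np.std(hi.action.p1) <= np.std(lo.action.p1) + 1e-9

    def test_deterministic_given_seed(self, fast_params, trained_weights):
        w = trained_weights.as_vector()[None, :]
        a = estimate_selection_probabilities(w, fast_params, 50, seed=7)
        b = estimate_selection_probabilities(w, fast_params, 50, seed=7)
        np.testing.assert_array_equal(a.action.p1, b.action.p1)

    def test_rejects_empty_input(self, fast_params):
        with pytest.raises(ValueError):
            estimate_selection_probabilities(np.empty((0, 8)), fast_params,
                                             10, seed=0)


class TestCompareGroups:
    def test_identical_samples_give_midpoint(self):
        a = np.arange(100, dtype=float)
        r = compare_groups(a, a.copy())
        assert r.u == pytest.approx(5000.0)

    def test_complete_separation(self):
        a = np.linspace(1, 2, 100)
        b = np.linspace(-2, 0, 100)
        r = compare_groups(a, b)
        assert r.u == 10000.0
        assert r.p_value < 1e-30

    def test_orientation_documented(self):
        r = compare_groups([1, 2, 3], [4, 5, 6])
        assert r.u == 0.0  # counts pairs where a exceeds b

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            assert compare_groups(a, b).u == pytest.approx(
                brute_force_u(a, b))

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=10),
           st.lists(st.integers(-50, 50), min_size=2, max_size=10),
           st.integers(-100, 100))
    def test_bounds_and_shift_invariance(self, a, b, c):
        # integer-valued floats keep the shift exact in binary
        a = [float(x) for x in a]
        b = [float(x) for x in b]
        r = compare_groups(a, b)
        assert 0.0 <= r.u <= len(a) * len(b)
        shifted = compare_groups([x + c for x in a], [x + c for x in b])
        assert shifted.u == pytest.approx(r.u)

    def test_bonferroni_adjustment(self):
        r = compare_groups([1.0, 2.0], [3.0, 4.0], n_comparisons=4)
        assert r.adjusted_alpha == pytest.approx(0.0125)
        r7 = compare_groups([1.0, 2.0], [3.0, 4.0], n_comparisons=7)
        assert r7.adjusted_alpha == pytest.approx(0.05 / 7)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
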