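"""Unit and property tests for the streaming median estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from medstream.estimators import (
    MedianCellArray,
    MovingMedian,
    NMEstimator,
    QuantileCascade,
    make_estimator,
    sliding_median_oracle,
)

finite_floats = st.floats(allow_nan=False, allow_infinity=False, width=32)


class TestNMBasics:
    @pytest.mark.parametrize(
        "samples, expected_buffer, expected_estimate",
        [
            ([3, 1, 2], [1, 2, 3], 2),
            ([5, 5, 5, 5, 5], [5, 5, 5, 5, 5], 5),
            ([1, 2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6, 7], 4),
        ],
    )
    def test_initial_fill_sorts_and_centers(self, samples, expected_buffer, expected_estimate):
        est = NMEstimator.from_samples(samples)
        assert est.buffer.tolist() == expected_buffer
        assert est.estimate == expected_estimate
        assert est.is_full

    def test_worked_example_two_updates(self):
        """Inserting 2 then 4 into [1..7]: estimates 3 then 4, dropping 7 then 1."""
        est = NMEstimator.from_samples([1, 2, 3, 4, 5, 6, 7])
        assert est.push(2) == 3
        assert est.buffer.tolist() == [1, 2, 2, 3, 4, 5, 6]
        assert est.push(4) == 4
        assert est.buffer.tolist() == [2, 2, 3, 4, 4, 5, 6]

    def test_new_minimum_inserted_at_beginning(self):
        est = NMEstimator.from_samples([1, 2, 3])
        assert est.push(0) == 1
        assert est.buffer.tolist() == [0, 1, 2]

    def test_tie_alternates_dropped_extreme(self):
        est = NMEstimator.from_samples([1, 2, 3])
        assert est.tie_toggle == 0
        assert est.push(2) == 2          # toggle 0: drop the max
        assert est.buffer.tolist() == [1, 2, 2]
        assert est.tie_toggle == 1
        assert est.push(2) == 2          # toggle 1: drop the min
        assert est.buffer.tolist() == [2, 2, 2]
        assert est.tie_toggle == 0

    def test_warmup_reports_lower_middle(self):
        est = NMEstimator(5)
        assert est.push(10) == 10
        assert est.push(2) == 2          # lower middle of [2, 10]
        assert est.push(5) == 5
        assert not est.is_full
        est.push(7), est.push(1)
        assert est.is_full
        assert est.estimate == 5

    @pytest.mark.parametrize("length", [0, 1, 2, 4, 10, -3])
    def test_invalid_length_rejected(self, length):
        with pytest.raises(ValueError):
            NMEstimator(length)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_samples_rejected(self, bad):
        est = NMEstimator.from_samples([1, 2, 3])
        with pytest.raises(ValueError):
            est.push(bad)
        with pytest.raises(ValueError):
            est.stream([0.0, bad])

    def test_random_tie_mode_is_seed_deterministic(self, rng):
        xs = np.round(rng.normal(size=500), 1)  # coarse grid forces ties
        a = NMEstimator(15, tie_break="random", seed=7).stream(xs)
        b = NMEstimator(15, tie_break="random", seed=7).stream(xs)
        c = NMEstimator(15, tie_break="random", seed=8).stream(xs)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestStreamPushEquivalence:
    """The compiled kernels must replay the pure-Python updates exactly."""

    @pytest.mark.parametrize("backend", ["nm", "cmm"])
    @pytest.mark.parametrize("length", [3, 15, 63])
    def test_kernel_matches_push(self, backend, length, rng):
        xs = np.round(rng.normal(size=1500), 1)  # duplicates exercise tie paths
        a = make_estimator(backend, length)
        b = make_estimator(backend, length)
        pushed = np.array([a.push(x) for x in xs])
        streamed = b.stream(xs)
        assert np.array_equal(pushed, streamed)
        assert np.array_equal(a.buffer, b.buffer)

    def test_kernel_matches_push_random_ties(self, rng):
        xs = np.round(rng.normal(size=800), 1)
        a = NMEstimator(15, tie_break="random", seed=3)
        b = NMEstimator(15, tie_break="random", seed=3)
        pushed = np.array([a.push(x) for x in xs])
        assert np.array_equal(pushed, b.stream(xs))

    def test_stream_resumes_across_segments(self, rng):
        xs = rng.normal(size=400)
        whole = make_estimator("nm", 31).stream(xs)
        est = make_estimator("nm", 31)
        parts = np.concatenate([est.stream(xs[:100]), est.stream(xs[100:])])
        assert np.array_equal(whole, parts)


class TestMovingMedian:
    def test_worked_example_evicts_oldest(self):
        # same sorted contents as the NM worked example, but 7 arrived first
        cmm = MovingMedian.from_samples([7, 6, 5, 4, 3, 2, 1])
        assert cmm.push(2) == 3  # 7 evicted -> sorted [1,2,2,3,4,5,6]
        assert cmm.buffer.tolist() == [1, 2, 2, 3, 4, 5, 6]
        assert cmm.window.tolist() == [6, 5, 4, 3, 2, 1, 2]

    def test_constant_window_median(self):
        cmm = MovingMedian.from_samples([4.0] * 5)
        assert cmm.push(4.0) == 4.0

    @pytest.mark.parametrize("length", [5, 31])
    def test_matches_sliding_oracle(self, length, rng):
        sig = rng.normal(size=500)
        trace = MovingMedian(length).stream(sig)
        oracle = sliding_median_oracle(sig, length)
        assert np.array_equal(trace[length - 1:], oracle)

    def test_oracle_hand_example(self):
        assert sliding_median_oracle([1, 9, 2, 8, 3], 3).tolist() == [2, 8, 3]

    def test_oracle_constant_signal(self):
        assert np.all(sliding_median_oracle([2.5] * 10, 5) == 2.5)

    def test_oracle_rejects_even_window(self):
        with pytest.raises(ValueError):
            sliding_median_oracle([1, 2, 3, 4], 2)


class TestInvariants:
    @given(st.lists(finite_floats, min_size=20, max_size=80))
    def test_buffer_always_sorted_and_bounded(self, xs):
        est = NMEstimator(7)
        lo, hi = np.inf, -np.inf
        for x in xs:
            est.push(x)
            lo, hi = min(lo, x), max(hi, x)
            buf = est.buffer
            assert np.all(np.diff(buf) >= 0)
            assert lo <= est.estimate <= hi

    @given(st.lists(st.integers(-5, 5), min_size=11, max_size=60))
    def test_cmm_equals_oracle_on_tie_heavy_input(self, xs):
        xs = np.array(xs, dtype=float)
        trace = MovingMedian(11).stream(xs)
        assert np.array_equal(trace[10:], sliding_median_oracle(xs, 11))

    def test_sortedness_long_random_streams(self, rng):
        for length in (15, 63):
            est = NMEstimator(length)
            est.stream(rng.normal(size=length))
            for _ in range(10):
                est.stream(rng.normal(size=10_000))
                assert np.all(np.diff(est.buffer) >= 0)

    @pytest.mark.parametrize(
        "dist, median",
        [(lambda r, n: r.normal(2.0, 1.0, n), 2.0),
         (lambda r, n: r.beta(1.5, 4.0, n), 0.24386443904578325)],
    )
    def test_estimator_is_unbiased(self, dist, median):
        """Mean steady-state error over many independent runs is zero."""
        n_runs, L = 5000, 15
        finals = np.empty(n_runs)
        for i, seed in enumerate(np.random.SeedSequence(42).spawn(n_runs)):
            r = np.random.default_rng(seed)
            est = NMEstimator(L)
            finals[i] = est.stream(dist(r, L + 10 * L))[-1]
        err = finals - median
        assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(n_runs)


class TestHardwareCellModel:
    def test_worked_example(self):
        arr = MedianCellArray([1, 2, 3, 4, 5, 6, 7])
        assert arr.step(2.0, 0) == 3.0
        assert arr.registers.tolist() == [1, 2, 2, 3, 4, 5, 6]
        assert arr.step(4.0, 0) == 4.0
        assert arr.registers.tolist() == [2, 2, 3, 4, 4, 5, 6]

    def test_tie_select_shifts_chosen_half(self):
        left = MedianCellArray([1, 2, 3, 4, 5])
        left.step(3.0, 1)  # drop the first value: left half shifts left
        assert left.registers.tolist() == [2, 3, 3, 4, 5]
        right = MedianCellArray([1, 2, 3, 4, 5])
        right.step(3.0, 0)  # drop the last value: right half shifts right
        assert right.registers.tolist() == [1, 2, 3, 3, 4]

    def test_central_signals_mutually_exclusive(self, rng):
        arr = MedianCellArray(np.sort(rng.integers(0, 10, 7)).astype(float))
        for x in rng.integers(-2, 12, 50).astype(float):
            assert sum(arr.central_signals(x)) == 1
            arr.step(x, 0)

    def test_registers_stay_sorted(self, rng):
        arr = MedianCellArray(np.sort(rng.normal(size=15)))
        for x in rng.normal(size=2000):
            arr.step(x, 0)
            assert np.all(np.diff(arr.registers) >= 0)

    def test_lockstep_equivalence_with_nm(self, rng):
        """10^4 random steps: register file identical to the NM buffer when
        the tie decisions are shared."""
        L = 15
        init = np.round(rng.normal(size=L), 1)
        est = NMEstimator.from_samples(init)
        arr = MedianCellArray(np.sort(init))
        for x in np.round(rng.normal(size=10_000), 1):
            s_bit = est.tie_toggle  # 1 = drop first, matching the S input
            out_nm = est.push(x)
            out_hw = arr.step(x, s_bit)
            assert out_hw == out_nm
            assert np.array_equal(arr.registers, est.buffer)


class TestQuantileCascade:
    def test_constant_stream(self):
        qc = QuantileCascade(5)
        for _ in range(100):
            q = qc.push(3.0)
        assert q == (3.0, 3.0, 3.0)

    def test_uniform_quartiles(self, rng):
        qc = QuantileCascade(63)
        out = [qc.push(x) for x in rng.uniform(0, 1, 40_000)]
        q25, q50, q75 = out[-1]
        assert abs(q25 - 0.25) < 0.05
        assert abs(q50 - 0.50) < 0.05
        assert abs(q75 - 0.75) < 0.05

    def test_gaussian_symmetry(self, rng):
        qc = QuantileCascade(63)
        for x in rng.normal(size=40_000):
            q25, q50, q75 = qc.push(x)
        assert abs(q50) < 0.06
        assert abs(q25 + q75) < 0.12  # quartiles mirror about the median
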