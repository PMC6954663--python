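import numpy as np
import pytest

from foldevents import (
    ReactivityMatrix,
    ThresholdSet,
    autotune,
    compute_signals,
    detect_swings,
    smooth,
)
from foldevents.swings import (
    base_thresholds_from_data,
    closest_to_origin,
    consensus_flag_count,
    default_alpha_grid,
    flag_cells,
)

from conftest import column_series, random_matrix, step_matrix
from oracle import oracle_closest_to_origin, oracle_flags, oracle_signals


class TestThresholdSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            ThresholdSet(0, 1, 1, 1, 1, 1)  # p_up must be > 0
        with pytest.raises(ValueError):
            ThresholdSet(1, 1, 1, 1, 1, 1, w_smooth=2)  # even window
        with pytest.raises(ValueError):
            ThresholdSet(1, 1, 1, 1, 1, 1, i_length=0)
        ThresholdSet(1, 1, 1, 1, 1, 1, m_floor=0.0)  # zero floor is legal

    def test_scaled_touches_only_the_seven(self, default_ts):
        s = default_ts.scaled(2.0)
        assert s.p_up == 0.6 and s.i_down == 1.2 and s.m_floor == 0.4
        assert s.w_smooth == default_ts.w_smooth
        assert s.i_length == default_ts.i_length

    def test_dict_round_trip(self, default_ts):
        assert ThresholdSet.from_dict(default_ts.to_dict()) == default_ts
        with pytest.raises(ValueError):
            ThresholdSet.from_dict({"p_up": 1, "bogus": 2})


class TestSmooth:
    def test_constant_series(self):
        out = smooth(np.full(10, 3.7), 3)
        np.testing.assert_allclose(out, 3.7)

    def test_hand_computed_truncated_means(self):
        out = smooth(np.array([0.0, 0.0, 3.0, 0.0, 0.0]), 3)
        np.testing.assert_allclose(out, [0.0, 1.0, 1.0, 1.0, 0.0])

    def test_w1_identity(self, rng):
        series = rng.gamma(1, 1, size=20)
        np.testing.assert_array_equal(smooth(series, 1), series)

    def test_empty_series(self):
        assert smooth(np.array([]), 3).size == 0

    def test_nan_splits_runs(self):
        series = np.array([1.0, 1.0, np.nan, 5.0, 5.0])
        out = smooth(series, 3)
        np.testing.assert_allclose(out[[0, 1]], 1.0)
        assert np.isnan(out[2])
        np.testing.assert_allclose(out[[3, 4]], 5.0)

    def test_matches_oracle_on_random_series(self, rng):
        from oracle import oracle_smooth

        for _ in range(20):
            series = rng.gamma(1, 1, size=rng.integers(1, 30))
            series[rng.random(series.size) < 0.2] = np.nan
            for w in (1, 3, 5):
                got = smooth(series, w)
                want = oracle_smooth(
                    [None if np.isnan(v) else v for v in series], w
                )
                for g, x in zip(got, want):
                    if x is None:
                        assert np.isnan(g)
                    else:
                        assert g == pytest.approx(x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.ones(5), 4)


class TestComputeSignals:
    def test_constant_column(self, default_ts):
        m = ReactivityMatrix(np.arange(30, 60), np.array([1]),
                             np.full((30, 1), 0.8))
        sig = compute_signals(m, default_ts)
        defined = ~np.isnan(sig.proportional[:, 0])
        assert defined.sum() > 0
        np.testing.assert_allclose(sig.proportional[defined, 0], 0.0, atol=1e-12)
        g_def = ~np.isnan(sig.integral[:, 0])
        np.testing.assert_allclose(sig.integral[g_def, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(sig.relative[defined, 0], 1.0)

    def test_step_column_worked_example(self):
        # 0.2 -> 1.5 step at length 50, no smoothing, i_length 5:
        # e at the step row is 1.5 - 0.2 = 1.3 and g accumulates it
        ts = ThresholdSet(0.3, 0.3, 0.6, 0.6, 0.5, 0.5, w_smooth=1, i_length=5)
        m = step_matrix()
        sig = compute_signals(m, ts)
        i50 = int(np.flatnonzero(m.lengths == 50)[0])
        assert sig.proportional[i50, 0] == pytest.approx(1.3)
        # brute-force evaluation of the formulas (frozen from tests/oracle.py):
        # the baseline absorbs the step, so e decays 1.3, 1.04, 0.78, ... and
        # the trailing integral climbs for the 5 rows after the step
        g = sig.integral[i50 : i50 + 6, 0]
        np.testing.assert_allclose(g[:5], [1.3, 2.34, 3.12, 3.64, 3.9])
        assert np.all(np.diff(g[:5]) > 0)
        assert g[5] < g[4]  # then the window slides past the step
        o = oracle_signals(column_series(m, 1), 1, 5)
        np.testing.assert_allclose(g[:5], o[3][i50 : i50 + 5])

    def test_short_column_yields_no_signal(self):
        # 3 defined lengths with i_length=5: not enough history anywhere
        ts = ThresholdSet(0.3, 0.3, 0.6, 0.6, 0.5, 0.5, i_length=5)
        m = ReactivityMatrix(np.arange(50, 53), np.array([1]),
                             np.array([[0.5], [1.5], [0.5]]))
        sig = compute_signals(m, ts)
        assert np.all(np.isnan(sig.proportional))
        assert np.all(np.isnan(sig.integral))

    def test_matches_oracle(self, rng, default_ts):
        for _ in range(30):
            m = random_matrix(rng, na_fraction=0.1)
            sig = compute_signals(m, default_ts)
            for j, pos in enumerate(m.positions):
                want = oracle_signals(
                    column_series(m, pos), default_ts.w_smooth, default_ts.i_length
                )
                for grid, ref in zip(
                    (sig.smoothed, sig.baseline, sig.proportional,
                     sig.integral, sig.relative),
                    want,
                ):
                    for i in range(m.lengths.size):
                        if ref[i] is None:
                            assert np.isnan(grid[i, j])
                        else:
                            assert grid[i, j] == pytest.approx(ref[i], abs=1e-9)


class TestDetectSwings:
    def test_constant_matrix_no_events(self, rng, default_ts):
        m = ReactivityMatrix(np.arange(20, 60), np.arange(1, 11),
                             np.full((40, 10), 1.0))
        assert len(detect_swings(m, default_ts)) == 0

    def test_step_yields_single_up_event(self):
        ts = ThresholdSet(0.3, 0.3, 0.6, 0.6, 0.5, 0.5, m_floor=0.2,
                          w_smooth=3, i_length=5, min_duration=2)
        m = step_matrix(low=0.2, high=1.5, step_at=50)
        events = detect_swings(m, ts)
        assert len(events) == 1
        (e,) = events
        assert e.direction == "up" and e.class_ == "swing"
        assert 49 <= e.start_length <= 51
        assert e.magnitude > 0

    def test_mirrored_step_yields_single_down_event(self):
        ts = ThresholdSet(0.3, 0.3, 0.6, 0.6, 0.5, 0.5, m_floor=0.2,
                          w_smooth=3, i_length=5, min_duration=2)
        m = step_matrix(low=1.5, high=0.2, step_at=50)  # high then low? no:
        # step_matrix steps *to* `high` at step_at; swap to get a drop
        events = detect_swings(m, ts)
        assert len(events) == 1
        (e,) = events
        assert e.direction == "down"
        assert 49 <= e.start_length <= 51
        assert e.magnitude < 0

    def test_no_event_starts_in_first_i_length_rows(self, rng, default_ts):
        for _ in range(30):
            m = random_matrix(rng, scale=2.0)
            events = detect_swings(m, default_ts)
            for e in events:
                col = m.column(e.nucleotide)
                first_defined = m.lengths[int(np.flatnonzero(~np.isnan(col))[0])]
                assert e.start_length >= first_defined + default_ts.i_length

    def test_min_duration_filters_short_runs(self):
        ts = ThresholdSet(0.3, 0.3, 0.6, 0.6, 0.5, 0.5, w_smooth=1,
                          i_length=5, min_duration=2, merge_gap=0)
        # single-length spike: flags at most one cell
        lengths = np.arange(30, 60)
        col = np.full(30, 0.2)
        col[15] = 3.0
        m = ReactivityMatrix(lengths, np.array([1]), col[:, None])
        assert len(detect_swings(m, ts)) == 0
        relaxed = ThresholdSet(0.3, 0.3, 0.6, 0.6, 0.5, 0.5, w_smooth=1,
                               i_length=5, min_duration=1, merge_gap=0, m_floor=0.2)
        assert len(detect_swings(m, relaxed)) >= 1

    def test_m_floor_filters_small_events(self):
        base = dict(w_smooth=1, i_length=5, min_duration=2)
        m = step_matrix(low=1.0, high=1.4, step_at=50)
        small = ThresholdSet(0.1, 0.1, 0.2, 0.2, 0.1, 0.1, m_floor=0.0, **base)
        assert len(detect_swings(m, small)) == 1
        floored = ThresholdSet(0.1, 0.1, 0.2, 0.2, 0.1, 0.1, m_floor=1.0, **base)
        assert len(detect_swings(m, floored)) == 0

    def test_events_cannot_span_undefined_cells(self):
        ts = ThresholdSet(0.1, 0.1, 0.2, 0.2, 0.1, 0.1, w_smooth=1,
                          i_length=3, min_duration=1, merge_gap=2, m_floor=0.0)
        lengths = np.arange(30, 60)
        col = np.concatenate([np.full(10, 0.2), np.full(20, 1.5)])
        col[12] = np.nan  # hole right after the step
        m = ReactivityMatrix(lengths, np.array([1]), col[:, None])
        for e in detect_swings(m, ts):
            idx = slice(
                int(np.flatnonzero(lengths == e.start_length)[0]),
                int(np.flatnonzero(lengths == e.end_length)[0]) + 1,
            )
            assert not np.any(np.isnan(col[idx]))


class TestFlagProperties:
    def test_oracle_equivalence(self, rng, default_ts):
        for _ in range(40):
            m = random_matrix(rng, na_fraction=0.05, scale=1.5)
            up, down = flag_cells(m, default_ts)
            for j, pos in enumerate(m.positions):
                o_up, o_down = oracle_flags(column_series(m, pos), default_ts)
                assert up[:, j].tolist() == o_up
                assert down[:, j].tolist() == o_down

    def test_monotonicity_in_scale(self, rng, default_ts):
        for _ in range(15):
            m = random_matrix(rng, scale=1.5)
            prev_up = prev_down = None
            for alpha in np.linspace(0.5, 3.0, 6):
                up, down = flag_cells(m, default_ts.scaled(alpha))
                if prev_up is not None:
                    assert np.all(up <= prev_up)
                    assert np.all(down <= prev_down)
                prev_up, prev_down = up, down

    def test_translation_leaves_e_g_unchanged(self, rng, default_ts):
        m = random_matrix(rng)
        shifted = ReactivityMatrix(m.lengths, m.positions, m.values + 2.0)
        a = compute_signals(m, default_ts)
        b = compute_signals(shifted, default_ts)
        np.testing.assert_allclose(a.proportional, b.proportional, atol=1e-9)
        np.testing.assert_allclose(a.integral, b.integral, atol=1e-9)
        # the relative channel must move
        defined = ~np.isnan(a.relative)
        assert not np.allclose(a.relative[defined], b.relative[defined])

    def test_scaling_multiplies_e_g_keeps_rel(self, rng, default_ts):
        m = random_matrix(rng)
        k = 3.0
        scaled = ReactivityMatrix(m.lengths, m.positions, m.values * k)
        a = compute_signals(m, default_ts)
        b = compute_signals(scaled, default_ts)
        np.testing.assert_allclose(b.proportional, a.proportional * k, atol=1e-9)
        np.testing.assert_allclose(b.integral, a.integral * k, atol=1e-9)
        defined = ~np.isnan(a.relative) & (a.baseline > 1e-3)
        np.testing.assert_allclose(b.relative[defined], a.relative[defined], rtol=1e-6)


class TestAutotune:
    def test_worked_decreasing_curve(self):
        alphas = np.arange(1.0, 11.0)
        counts = np.array([100, 40, 18, 10, 7, 5, 4, 3, 2, 1], dtype=float)
        got = closest_to_origin(alphas, counts)
        want = oracle_closest_to_origin(alphas, counts)
        assert got == want

    def test_constant_counts_pick_smallest_alpha(self):
        alphas = np.arange(1.0, 6.0)
        counts = np.full(5, 7.0)
        assert closest_to_origin(alphas, counts) == 0

    def test_all_zero_counts_warn_and_return_smallest(self, default_ts):
        m = ReactivityMatrix(np.arange(20, 60), np.arange(1, 6),
                             np.full((40, 5), 1.0))
        grid = [0.5, 1.0, 2.0]
        chosen = autotune([m], grid=grid, base=default_ts)
        assert chosen.p_up == pytest.approx(default_ts.p_up * 0.5)

    def test_flag_count_non_increasing_in_alpha(self, rng, default_ts):
        m = random_matrix(rng, scale=1.5)
        counts = [
            consensus_flag_count([m], default_ts.scaled(a))
            for a in default_alpha_grid(10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_autotune_returns_scaled_base(self, rng):
        m = random_matrix(rng, n_lengths=30, n_positions=10, scale=2.0)
        base = base_thresholds_from_data([m])
        chosen, alphas, counts = autotune([m], base=base, return_curve=True)
        idx = oracle_closest_to_origin(alphas, counts) if counts.max() > 0 else 0
        assert chosen.p_up == pytest.approx(base.p_up * alphas[idx])

    def test_bad_grid_rejected(self, rng, default_ts):
        m = random_matrix(rng)
        with pytest.raises(ValueError):
            autotune([m], grid=[1.0, 2.0], base=default_ts)
        with pytest.raises(ValueError):
            autotune([m], grid=[2.0, 1.0, 3.0], base=default_ts)
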