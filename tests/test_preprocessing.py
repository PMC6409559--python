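import numpy as np
import pytest

import vo2fit as v


class TestTrimCardiodynamic:
    def test_half_open_removal_keeps_boundary_breath(self):
        s = v.BreathSeries(np.array([5.0, 15.0, 19.9, 20.0, 25.0]), np.full(5, 30.0))
        out = v.trim_cardiodynamic(s, 20.0)
        np.testing.assert_array_equal(out.time, [20.0, 25.0])
        assert out.edits[-1].indices_removed == (0, 1, 2)

    def test_zero_cutoff_is_identity(self, noisy_flat_series):
        out = v.trim_cardiodynamic(noisy_flat_series, 0.0)
        np.testing.assert_array_equal(out.vo2, noisy_flat_series.vo2)

    def test_removing_everything_is_an_error(self):
        s = v.BreathSeries(np.array([1.0, 5.0, 19.0]), np.full(3, 30.0))
        with pytest.raises(v.EmptySeriesError):
            v.trim_cardiodynamic(s, 20.0)


class TestRollingSdExclude:
    def _brute_force(self, vo2, window, k):
        """Independent recomputation of every window's mean/SD."""
        n, half = vo2.size, window // 2
        out = []
        for i in range(half, n - half):
            neigh = np.concatenate([vo2[i - half: i], vo2[i + 1: i + half + 1]])
            if abs(vo2[i] - neigh.mean()) > k * neigh.std(ddof=1):
                out.append(i)
        return tuple(out)

    def test_injected_spike_is_the_only_exclusion(self):
        rng = np.random.default_rng(1)
        vo2 = 30.0 + rng.normal(0.0, 1.0, 200)
        vo2[100] += 10.0  # +10 sigma errant breath
        s = v.BreathSeries(np.arange(200.0), np.maximum(vo2, 0.0))
        out, report = v.rolling_sd_exclude(s, window=15, k=4.0)
        assert report.indices_removed == self._brute_force(s.vo2, 15, 4.0)
        assert 100 in report.indices_removed
        assert report.n_after == report.n_before - len(report.indices_removed)

    def test_constant_series_untouched(self):
        s = v.BreathSeries(np.arange(50.0), np.full(50, 40.0))
        out, report = v.rolling_sd_exclude(s, window=15, k=4.0)
        assert report.indices_removed == ()
        np.testing.assert_array_equal(out.vo2, s.vo2)

    def test_huge_k_is_identity(self, noisy_flat_series):
        out, report = v.rolling_sd_exclude(noisy_flat_series, window=15, k=1e12)
        assert report.indices_removed == ()

    @pytest.mark.parametrize("k", [1.0, 2.0, 4.0])
    @pytest.mark.parametrize("model", ["mono_td", "bi_td", "tri", "logistic"])
    def test_noise_free_model_curves_never_filtered(self, model, k):
        series, _ = v.generate_series(v.GeneratorConfig(model=model))
        _, report = v.rolling_sd_exclude(series, window=15, k=k)
        assert report.indices_removed == ()

    def test_window_larger_than_series_rejected(self):
        s = v.BreathSeries(np.arange(5.0), np.full(5, 30.0))
        with pytest.raises(v.InvalidWindowError):
            v.rolling_sd_exclude(s, window=15)


class TestBoxAverage:
    def test_constant_series(self):
        s = v.BreathSeries(np.arange(0.0, 30.0), np.full(30, 40.0))
        out = v.box_average(s, 10.0)
        np.testing.assert_array_equal(out.time, [5.0, 15.0, 25.0])
        np.testing.assert_array_equal(out.vo2, [40.0, 40.0, 40.0])

    def test_single_bin_mean(self):
        t = np.arange(10.0)
        out = v.box_average(v.BreathSeries(t, t), 10.0)
        assert out.n == 1
        assert out.vo2[0] == pytest.approx(np.mean(range(10)))
        assert out.time[0] == 5.0

    def test_empty_bin_emits_no_sample(self):
        t = np.array([1.0, 2.0, 25.0, 26.0])  # nothing in [10, 20)
        out = v.box_average(v.BreathSeries(t, np.full(4, 30.0)), 10.0)
        np.testing.assert_array_equal(out.time, [5.0, 25.0])

    def test_non_positive_box_rejected(self, noisy_flat_series):
        with pytest.raises(v.InvalidInputError):
            v.box_average(noisy_flat_series, 0.0)


class TestMovingAverage:
    def test_window_one_is_identity(self, noisy_flat_series):
        out = v.moving_average(noisy_flat_series, 1)
        np.testing.assert_array_equal(out.vo2, noisy_flat_series.vo2)

    def test_centered_mean_with_symmetric_edge_shrink(self):
        s = v.BreathSeries(np.array([0.0, 1.0, 2.0]), np.array([10.0, 20.0, 30.0]))
        out = v.moving_average(s, 3)
        np.testing.assert_array_equal(out.vo2, [10.0, 20.0, 30.0])
        np.testing.assert_array_equal(out.time, s.time)

    def test_constant_series_unchanged(self):
        s = v.BreathSeries(np.arange(20.0), np.full(20, 35.0))
        np.testing.assert_array_equal(v.moving_average(s, 5).vo2, s.vo2)

    def test_even_window_rejected(self, noisy_flat_series):
        with pytest.raises(v.InvalidInputError):
            v.moving_average(noisy_flat_series, 4)


class TestInterpolate1s:
    def test_linear_interpolation_onto_integer_grid(self):
        s = v.BreathSeries(np.array([0.0, 2.0]), np.array([10.0, 20.0]))
        out = v.interpolate_1s(s)
        np.testing.assert_array_equal(out.time, [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(out.vo2, [10.0, 15.0, 20.0])

    def test_already_gridded_values_unchanged(self):
        t = np.arange(0.0, 50.0)
        s = v.BreathSeries(t, np.sqrt(t + 1.0))
        np.testing.assert_array_equal(v.interpolate_1s(s).vo2, s.vo2)

    def test_no_extrapolation_beyond_span(self):
        s = v.BreathSeries(np.array([0.4, 5.6]), np.array([10.0, 20.0]))
        out = v.interpolate_1s(s)
        assert out.t_start == 1.0 and out.t_end == 5.0

    def test_single_sample_rejected(self):
        s = v.BreathSeries(np.array([3.0]), np.array([10.0]))
        with pytest.raises(v.InsufficientDataError):
            v.interpolate_1s(s)


class TestEnsembleAverage:
    def test_identical_transitions_average_to_themselves(self):
        t = np.arange(0.0, 100.0)
        s = v.BreathSeries(t, 30.0 + t / 10.0)
        out = v.ensemble_average([s, s])
        np.testing.assert_array_equal(out.vo2, s.vo2)

    def test_mean_of_constant_transitions(self):
        t = np.arange(0.0, 50.0)
        a = v.BreathSeries(t, np.full(50, 30.0))
        b = v.BreathSeries(t, np.full(50, 50.0))
        np.testing.assert_array_equal(v.ensemble_average([a, b]).vo2, np.full(50, 40.0))

    def test_output_restricted_to_overlap(self):
        a = v.BreathSeries(np.arange(0.0, 101.0), np.full(101, 30.0))
        b = v.BreathSeries(np.arange(0.0, 81.0), np.full(81, 30.0))
        out = v.ensemble_average([a, b])
        assert out.t_start == 0.0 and out.t_end == 80.0

    def test_disjoint_transitions_rejected(self):
        a = v.BreathSeries(np.arange(0.0, 10.0), np.full(10, 30.0))
        b = v.BreathSeries(np.arange(50.0, 60.0), np.full(10, 30.0))
        with pytest.raises(v.NoOverlapError):
            v.ensemble_average([a, b])

    def test_single_transition_rejected(self, noisy_flat_series):
        with pytest.raises(v.InvalidInputError):
            v.ensemble_average([noisy_flat_series])


class TestDeletePoints:
    def test_delete_by_index(self, noisy_flat_series):
        out = v.delete_points(noisy_flat_series, indices=[0])
        assert out.n == noisy_flat_series.n - 1
        assert out.time[0] == noisy_flat_series.time[1]

    def test_delete_closed_time_range(self, noisy_flat_series):
        out = v.delete_points(noisy_flat_series, time_range=(100.0, 110.0))
        expected = noisy_flat_series.time[
            (noisy_flat_series.time < 100.0) | (noisy_flat_series.time > 110.0)
        ]
        np.testing.assert_array_equal(out.time, expected)

    def test_empty_deletion_is_identity(self, noisy_flat_series):
        assert v.delete_points(noisy_flat_series, indices=[]) is noisy_flat_series

    def test_out_of_range_index_lists_offenders(self, noisy_flat_series):
        with pytest.raises(v.InvalidInputError, match="999"):
            v.delete_points(noisy_flat_series, indices=[1, 999])


class TestEditLog:
    def test_replay_reproduces_processed_series_bit_exactly(self):
        rng = np.random.default_rng(5)
        raw = v.BreathSeries(
            np.sort(rng.uniform(0.0, 300.0, 250)),
            np.maximum(30.0 + rng.normal(0.0, 2.0, 250), 0.0),
        )
        s = v.trim_cardiodynamic(raw, 20.0)
        s, _ = v.rolling_sd_exclude(s, window=15, k=4.0)
        s = v.delete_points(s, indices=[3, 7])
        s = v.box_average(s, 10.0)
        s = v.moving_average(s, 3)
        replayed = v.replay(raw, s.edits)
        np.testing.assert_array_equal(replayed.time, s.time)
        np.testing.assert_array_equal(replayed.vo2, s.vo2)

    def test_edits_log_is_append_only(self, noisy_flat_series):
        a = v.trim_cardiodynamic(noisy_flat_series, 20.0)
        b = v.moving_average(a, 3)
        assert [e.op for e in b.edits] == ["trim_cardiodynamic", "moving_average"]
        assert b.edits[: len(a.edits)] == a.edits


class TestFilterInvariants:
    @pytest.mark.parametrize("apply", [
        lambda s: v.moving_average(s, 5),
        lambda s: v.box_average(s, 10.0),
        lambda s: v.interpolate_1s(s),
    ])
    def test_averaging_filters_stay_inside_input_range(self, apply, noisy_flat_series):
        out = apply(noisy_flat_series)
        assert out.vo2.min() >= noisy_flat_series.vo2.min() - 1e-12
        assert out.vo2.max() <= noisy_flat_series.vo2.max() + 1e-12
        assert np.all(np.diff(out.time) > 0)

    def test_trim_commutes_with_point_exclusion_filters(self):
        rng = np.random.default_rng(3)
        vo2 = 30.0 + rng.normal(0.0, 2.0, 300)
        vo2[150] += 25.0
        s = v.BreathSeries(np.arange(300.0), np.maximum(vo2, 0.0))
        a, _ = v.rolling_sd_exclude(v.trim_cardiodynamic(s, 20.0), 15, 4.0)
        b = v.trim_cardiodynamic(v.rolling_sd_exclude(s, 15, 4.0)[0], 20.0)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.vo2, b.vo2)
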