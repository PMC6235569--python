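"""Kymograph construction, folding, binning, integration, front fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epishear import (GridSpec, Kymograph, VelocityField, build_kymograph,
                      build_plank_kymographs, bin_kymograph, fold_kymograph,
                      fold_fields, integrate_displacement, mean_velocity_series,
                      estimate_propagation_speed, generate_velocity_series,
                      make_condition_preset)


def fields_from_array(values, grid, plank="top", component="y"):
    """Turn a (n_t, n_rows, n_cols) array into VelocityFields."""
    times = grid.frame_times()[: len(values)]
    out = []
    for t, frame in zip(times, values):
        zeros = np.zeros_like(frame)
        u, v = (frame, zeros) if component == "x" else (zeros, frame)
        out.append(VelocityField(time=float(t), plank=plank, u=u, v=v, grid=grid))
    return out


class TestBuild:
    def test_horizontal_mean_of_constant_columns(self, default_grid):
        frames = np.full((4, 15, 18), 30.0)
        k = build_kymograph(fields_from_array(frames, default_grid), "y")
        assert k.values.shape == (4, 15)
        assert np.all(k.values == 30.0)

    def test_single_hot_cell_averages_to_one(self, default_grid):
        frames = np.zeros((2, 15, 18))
        frames[1, 4, 7] = 18.0
        k = build_kymograph(fields_from_array(frames, default_grid), "y")
        assert k.values[1, 4] == pytest.approx(1.0)
        assert np.count_nonzero(k.values) == 1

    def test_default_grid_height_is_15(self, default_grid):
        frames = np.zeros((3, 15, 18))
        k = build_kymograph(fields_from_array(frames, default_grid), "x")
        assert len(k.y_positions) == 15

    def test_rejects_mixed_planks_and_empty(self, default_grid):
        f = fields_from_array(np.zeros((2, 15, 18)), default_grid)
        g = fields_from_array(np.zeros((2, 15, 18)), default_grid, plank="bottom")
        with pytest.raises(ValueError, match="plank"):
            build_kymograph([f[0], g[1]], "y")
        with pytest.raises(ValueError, match="empty"):
            build_kymograph([], "y")


class TestFold:
    def _pair(self, top_vals, bottom_vals, grid, component="y"):
        top = build_kymograph(
            fields_from_array(top_vals, grid, "top", component), component)
        bottom = build_kymograph(
            fields_from_array(bottom_vals, grid, "bottom", component), component)
        return top, bottom

    def test_antisymmetric_pair_folds_to_top(self, default_grid):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 15, 18))
        top, bottom = self._pair(vals, -vals, default_grid)
        folded = fold_kymograph(top, bottom)
        np.testing.assert_array_equal(folded.values, top.values)
        assert folded.folded

    def test_y_sign_flip_then_average(self, default_grid):
        plus = np.full((2, 15, 18), 5.0)
        top, bottom = self._pair(plus, -plus, default_grid)
        assert np.all(fold_kymograph(top, bottom).values == 5.0)
        top2, bottom2 = self._pair(plus, plus, default_grid)
        assert np.all(fold_kymograph(top2, bottom2).values == 0.0)

    def test_x_averages_without_flip(self, default_grid):
        plus = np.full((2, 15, 18), 5.0)
        top, bottom = self._pair(plus, plus, default_grid, component="x")
        assert np.all(fold_kymograph(top, bottom).values == 5.0)

    def test_shape_and_state_checks(self, default_grid):
        small = GridSpec(n_rows=4, n_cols=3, plank_height=80, field_width=60)
        top, bottom = self._pair(np.zeros((2, 15, 18)), np.zeros((2, 15, 18)),
                                 default_grid)
        other = build_kymograph(
            fields_from_array(np.zeros((2, 4, 3)), small, "bottom"), "y")
        with pytest.raises(ValueError, match="mismatch"):
            fold_kymograph(top, other)
        folded = fold_kymograph(top, bottom)
        with pytest.raises(ValueError, match="unfolded"):
            fold_kymograph(folded, bottom)


class TestBin:
    def test_block_mean(self, kymo_factory):
        k = kymo_factory([0, 1, 2], [10.0], [[10.0], [20.0], [30.0]])
        b = bin_kymograph(k, 3)
        assert b.values.shape == (1, 1) and b.values[0, 0] == 20.0
        assert b.times[0] == 1.0

    def test_identity_bin(self, kymo_factory):
        k = kymo_factory([0, 1, 2], [10.0], [[1.0], [2.0], [3.0]])
        np.testing.assert_array_equal(bin_kymograph(k, 1).values, k.values)

    def test_302_frames_make_101_bins(self, kymo_factory):
        vals = np.arange(302, dtype=float)[:, None]
        k = kymo_factory(np.arange(302.0), [10.0], vals)
        b = bin_kymograph(k, 3)
        assert b.values.shape == (101, 1)
        assert b.values[-1, 0] == pytest.approx((300 + 301) / 2)  # partial block
        assert b.bin_width == 3

    def test_oversized_bin_collapses_to_single(self, kymo_factory):
        k = kymo_factory([0, 1], [10.0], [[2.0], [4.0]])
        b = bin_kymograph(k, 10)
        assert b.values.shape == (1, 1) and b.values[0, 0] == 3.0

    @given(n=st.integers(1, 6), blocks=st.integers(1, 5), seed=st.integers(0, 10))
    def test_divisible_binning_equals_block_means(self, n, blocks, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n * blocks, 3))
        k = Kymograph(component="y", times=np.arange(n * blocks, dtype=float),
                      y_positions=np.array([5.0, 10.0, 15.0]), values=vals)
        b = bin_kymograph(k, n)
        np.testing.assert_allclose(b.values,
                                   vals.reshape(blocks, n, 3).mean(axis=1))


class TestIntegrate:
    def test_constant_velocity(self, kymo_factory):
        times = np.linspace(0, 2, 25)
        k = kymo_factory(times, [8.33], np.full((25, 1), 30.0), folded=True)
        traces = integrate_displacement(k, [8.0])
        assert traces.displacement[0, 0] == 0.0
        assert traces.displacement[-1, 0] == pytest.approx(60.0)

    def test_whole_period_sine_integrates_to_zero(self, kymo_factory):
        times = np.linspace(0, 8, 961)
        v = np.sin(2 * np.pi * times / 4)[:, None]
        k = kymo_factory(times, [8.33], v, folded=True)
        traces = integrate_displacement(k, [8.33])
        assert abs(traces.displacement[-1, 0]) < 1e-4

    def test_position_snapping(self, default_grid, kymo_factory):
        k = kymo_factory(np.linspace(0, 1, 5), default_grid.row_centers,
                         np.zeros((5, 15)), folded=True)
        traces = integrate_displacement(k, [8.0, 242.0])
        assert traces.y_positions[0] == pytest.approx(250 / 15 / 2)  # 8.33
        assert traces.y_positions[1] == pytest.approx(241.6667, abs=1e-3)
        with pytest.raises(ValueError, match="valid positions"):
            integrate_displacement(k, [300.0])

    def test_linearity(self, kymo_factory):
        rng = np.random.default_rng(1)
        times = np.linspace(0, 5, 61)
        v1 = rng.normal(size=(61, 2))
        v2 = rng.normal(size=(61, 2))
        pos = [10.0, 30.0]
        mk = lambda v: kymo_factory(times, pos, v, folded=True)
        d1 = integrate_displacement(mk(v1), pos).displacement
        d2 = integrate_displacement(mk(v2), pos).displacement
        d12 = integrate_displacement(mk(2 * v1 + 3 * v2), pos).displacement
        np.testing.assert_allclose(d12, 2 * d1 + 3 * d2, atol=1e-10)

    def test_bin_then_integrate_commutes_on_smooth_field(self, kymo_factory):
        times = np.arange(0, 20, 1 / 12)
        v = (10 * np.exp(-times / 10) * np.sin(2 * np.pi * times / 8))[:, None]
        k = kymo_factory(times, [100.0], v, folded=True)
        a = integrate_displacement(bin_kymograph(k, 3), [100.0])
        b = integrate_displacement(k, [100.0])
        # compare at the end of the window; trapezoid error bound on smooth data
        assert a.displacement[-1, 0] == pytest.approx(b.displacement[-1, 0], abs=0.3)


class TestMeanSeries:
    def test_constant_rows(self, kymo_factory):
        k = kymo_factory([0, 1], [5.0, 10.0], np.full((2, 2), 3.0), folded=True)
        np.testing.assert_array_equal(mean_velocity_series(k).mean_v, [3.0, 3.0])

    def test_balanced_rows_cancel(self, kymo_factory):
        k = kymo_factory([0.0], [5.0, 10.0], [[+4.0, -4.0]], folded=True)
        assert mean_velocity_series(k).mean_v[0] == 0.0

    def test_linear_in_y_field(self, default_grid, kymo_factory):
        centers = default_grid.row_centers
        k = kymo_factory([0.0], centers, centers[None, :], folded=True)
        assert mean_velocity_series(k).mean_v[0] == pytest.approx(125.0)

    def test_requires_folded(self, kymo_factory):
        k = kymo_factory([0.0], [5.0], [[1.0]], folded=False)
        with pytest.raises(ValueError, match="folded"):
            mean_velocity_series(k)


class TestPropagationSpeed:
    @pytest.mark.parametrize("speed", [50.0, 120.0, 290.0, 500.0])
    def test_recovers_generating_wave_speed(self, speed):
        """Front recovery within 5% across the physiological speed range."""
        p = make_condition_preset("+Shear", noise_sd=0.0, wave_speed_initial=speed)
        fields, _ = generate_velocity_series(p, seed=0)
        fit = estimate_propagation_speed(fold_fields(fields, "y"))
        assert fit.speed == pytest.approx(speed, rel=0.05)
        assert fit.r_squared > 0.95

    def test_simultaneous_onset_returns_inf(self, kymo_factory):
        times = np.linspace(0, 2, 25)
        vals = np.where(times[:, None] >= 1.0, -10.0, 0.0) * np.ones((1, 5))
        k = kymo_factory(times, [10, 20, 30, 40, 50], vals, folded=True)
        with pytest.warns(UserWarning, match="simultaneous onset"):
            fit = estimate_propagation_speed(k)
        assert np.isinf(fit.speed)

    def test_no_front_errors(self, kymo_factory):
        k = kymo_factory(np.linspace(0, 2, 25), [10.0, 20.0, 30.0],
                         np.zeros((25, 3)), folded=True)
        with pytest.raises(ValueError, match="no propagating front"):
            estimate_propagation_speed(k)
        # outward-only wave: inward onset never fires
        k2 = kymo_factory(np.linspace(0, 2, 25), [10.0, 20.0, 30.0],
                          np.full((25, 3), +5.0), folded=True)
        with pytest.raises(ValueError, match="no propagating front"):
            estimate_propagation_speed(k2)


class TestRoundTrips:
    def test_fold_fields_matches_manual_path(self, shear_preset):
        fields, _ = generate_velocity_series(shear_preset, seed=2)
        manual = build_plank_kymographs(fields, "y")
        auto = fold_fields(fields, "y")
        np.testing.assert_array_equal(
            auto.values,
            fold_kymograph(manual["top"], manual["bottom"]).values)

    def test_kymograph_csv_round_trip(self, tmp_path, kymo_factory):
        import pandas as pd

        k = kymo_factory([0.0, 0.5], [8.33, 25.0], [[1.0, 2.0], [3.0, 4.0]],
                         folded=True)
        path = tmp_path / "kymo.csv"
        k.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_h", "8.33", "25.00"]
        np.testing.assert_allclose(df.iloc[:, 1:].to_numpy(), k.values)
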