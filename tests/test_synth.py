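"""Synthetic generator: presets, closed-form signal, determinism, sidecars."""

import json
import math

import numpy as np
import pytest

from epishear import (GridSpec, GroundTruth, make_condition_preset,
                      generate_sensing_trace, generate_velocity_series)
from epishear.presets import CONDITION_NAMES
from epishear.synth import amplitude_ramp, v_signal


class TestPresets:
    def test_shear_preset_carries_study_values(self):
        p = make_condition_preset("+Shear")
        assert p.osc_amplitude == 30.0
        assert p.osc_period == 8.0
        assert p.first_reversal == 7.0
        assert p.wave_speed_initial == 290.0
        assert p.wave_speed_reversal == 90.0
        assert p.tau_force == 3.7
        assert p.deform_zone_width == 50.0
        assert p.f_ext_to_f_int == 4.0

    def test_no_shear_preset(self):
        p = make_condition_preset("-Shear")
        assert p.osc_amplitude == 9.0
        assert p.deform_peak_speed == 0.0
        assert p.tau_force is None

    def test_jasp_preset(self):
        p = make_condition_preset("+Jasp")
        assert p.osc_amplitude == 10.0
        assert math.isinf(p.osc_damping_D)
        assert p.wave_speed_initial == 80.0
        assert p.tau_force == 6.2

    @pytest.mark.parametrize("name,tau", [("+Blebb", 1.3), ("T151", 3.7)])
    def test_non_oscillatory_presets(self, name, tau):
        p = make_condition_preset(name)
        assert p.osc_amplitude == 0.0
        assert p.wave_speed_initial == 0.0
        assert p.tau_force == tau

    def test_unknown_condition_lists_supported(self):
        with pytest.raises(ValueError, match="supported conditions"):
            make_condition_preset("+Latrunculin")
        # all supported names appear in the message
        with pytest.raises(ValueError, match="T151"):
            make_condition_preset("nope")

    def test_overrides_and_validation(self):
        p = make_condition_preset("+Shear", noise_sd=0.0, osc_amplitude=12.0)
        assert p.noise_sd == 0.0 and p.osc_amplitude == 12.0
        with pytest.raises(ValueError, match="unknown preset override"):
            make_condition_preset("+Shear", wibble=1)
        with pytest.raises(ValueError, match="noise_sd"):
            make_condition_preset("+Shear", noise_sd=-1.0)

    def test_all_conditions_construct(self):
        for name in CONDITION_NAMES:
            assert make_condition_preset(name).name == name


class TestVelocitySeries:
    def test_grid_row_centers(self, default_grid):
        centers = default_grid.row_centers
        assert len(centers) == 15
        assert centers[0] == pytest.approx(250 / 15 / 2)      # ~8.33 um
        assert centers[-1] == pytest.approx(250 - 250 / 15 / 2)  # ~241.67 um
        times = default_grid.frame_times()
        assert times[0] == -1.0 and times[-1] == pytest.approx(23.25)
        assert np.all(np.diff(times) > 0)

    def test_wave_onset_at_outermost_row(self, noiseless_shear, default_grid):
        """No y-motion at 241.7 um before the front arrives at y/290 h."""
        fields, _ = generate_velocity_series(noiseless_shear, seed=0)
        t_on = default_grid.row_centers[-1] / 290.0  # ~0.833 h
        top = [f for f in fields if f.plank == "top"]
        before = [f for f in top if f.time < t_on]
        after = [f for f in top if f.time >= t_on]
        assert all(np.all(f.v[-1] == 0) for f in before)
        assert np.any(np.abs(after[0].v[-1]) > 0)

    def test_pre_shear_frames_are_quiet(self, noiseless_shear):
        fields, _ = generate_velocity_series(noiseless_shear, seed=0)
        for f in fields:
            if f.time < 0:
                assert np.all(f.v == 0) and np.all(f.u == 0)

    def test_null_signal_gives_zero_fields(self):
        p = make_condition_preset("+Shear", osc_amplitude=0.0,
                                  deform_peak_speed=0.0, noise_sd=0.0)
        fields, _ = generate_velocity_series(p, seed=1)
        assert all(np.all(f.u == 0) and np.all(f.v == 0) for f in fields)

    def test_seeded_determinism_and_seed_sensitivity(self, shear_preset):
        a, _ = generate_velocity_series(shear_preset, seed=11)
        b, _ = generate_velocity_series(shear_preset, seed=11)
        c, _ = generate_velocity_series(shear_preset, seed=12)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.v, fb.v)
            np.testing.assert_array_equal(fa.u, fb.u)
        assert any(not np.array_equal(fa.v, fc.v) for fa, fc in zip(a, c))

    def test_antisymmetric_planks_without_noise(self, noiseless_shear):
        fields, _ = generate_velocity_series(noiseless_shear, seed=0)
        by_time = {}
        for f in fields:
            by_time.setdefault(f.time, {})[f.plank] = f
        for planks in by_time.values():
            np.testing.assert_array_equal(planks["top"].v, -planks["bottom"].v)
            np.testing.assert_array_equal(planks["top"].u, planks["bottom"].u)

    def test_noiseless_values_match_closed_form(self, noiseless_shear, default_grid):
        """Spot-check the generator against an independent re-derivation."""
        p = noiseless_shear
        fields, truth = generate_velocity_series(p, seed=0)
        ramp = amplitude_ramp(default_grid)
        y = default_grid.row_centers
        y_ref = float(np.sum(ramp * y) / np.sum(ramp))
        top = [f for f in fields if f.plank == "top"]
        for row in (0, 7, 14):
            yy = y[row]
            t_on = yy / p.wave_speed_initial
            r1 = p.first_reversal + (yy - y_ref) / p.wave_speed_reversal
            for f in (top[5], top[30], top[120], top[250]):
                t = f.time
                if t < t_on:
                    expect = 0.0
                elif t < r1:
                    expect = (-p.osc_amplitude * ramp[row]
                              * math.exp(-t / (2 * p.osc_damping_D))
                              * math.cos(0.5 * math.pi * (t - t_on) / (r1 - t_on)))
                else:
                    expect = (p.osc_amplitude * ramp[row]
                              * math.exp(-t / (2 * p.osc_damping_D))
                              * math.sin(2 * math.pi * (t - r1) / p.osc_period))
                assert f.v[row, 0] == pytest.approx(expect, abs=1e-12)

    def test_deformation_zone_confined_and_transient(self, noiseless_shear, default_grid):
        fields, _ = generate_velocity_series(noiseless_shear, seed=0)
        zone_rows = default_grid.row_centers < noiseless_shear.deform_zone_width
        for f in fields:
            if 0 <= f.time < 1.0:
                assert np.all(f.u[zone_rows] <= 0)       # opposite the shear
                assert np.all(f.u[~zone_rows] == 0)      # confined to the zone
            if f.time > 3.0:
                assert np.all(f.u == 0)                  # ceased by ~3 h

    def test_amplitude_grows_away_from_shear_plane(self, default_grid):
        p = make_condition_preset("+Shear", noise_sd=0.0)
        sig = v_signal(default_grid.frame_times(), default_grid, p)
        peak_by_row = np.max(np.abs(sig), axis=0)
        assert np.all(np.diff(peak_by_row) > 0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GridSpec(n_rows=0)


class TestGroundTruth:
    def test_json_round_trip(self, tmp_path, shear_preset):
        _, truth = generate_velocity_series(shear_preset, seed=5)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded.to_dict() == truth.to_dict()
        # and the file is plain JSON
        assert json.loads(path.read_text())["seed"] == 5


class TestSensingTrace:
    def test_zero_before_shear(self, shear_preset):
        trace, _ = generate_sensing_trace(shear_preset, noise_sd_um=0.0)
        assert np.all(trace.displacement[trace.times < 0] == 0)

    def test_tau_decay_fraction(self, shear_preset):
        """At t = tau the trace has decayed by 63.2% of (peak - plateau)."""
        trace, truth = generate_sensing_trace(shear_preset, f_max=1.0,
                                              noise_sd_um=0.0,
                                              sample_interval_s=1.0)
        tau_s = shear_preset.tau_force * 60.0
        peak = truth.params["peak_displacement_um"]
        plateau = 0.2 * peak
        d_tau = trace.displacement[np.searchsorted(trace.times, tau_s)]
        frac = (peak - d_tau) / (peak - plateau)
        assert frac == pytest.approx(1 - math.exp(-1), abs=1e-4)

    def test_full_relaxation_without_plateau(self, shear_preset):
        trace, _ = generate_sensing_trace(shear_preset, plateau=0.0,
                                          noise_sd_um=0.0, t_end_min=200.0)
        assert abs(trace.displacement[-1]) < 1e-8

    def test_missing_tau_errors(self):
        p = make_condition_preset("-Shear")
        with pytest.raises(ValueError, match="skip the force stage"):
            generate_sensing_trace(p)

    def test_cadence_and_span(self, shear_preset):
        trace, _ = generate_sensing_trace(shear_preset, noise_sd_um=0.0)
        assert trace.times[0] == -300.0 and trace.times[-1] == 1800.0
        assert np.all(np.diff(trace.times) == 30.0)

    def test_csv_round_trip(self, tmp_path, shear_preset):
        from epishear import SensingDisplacementTrace

        trace, _ = generate_sensing_trace(shear_preset, seed=9)
        path = tmp_path / "sensing.csv"
        trace.to_csv(path)
        loaded = SensingDisplacementTrace.from_csv(path)
        np.testing.assert_allclose(loaded.displacement, trace.displacement)
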