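"""Tests for RCS mapping/profiling, WF tracking, timing and ROI statistics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depotflow import imaging as I
from depotflow import quantify as Q
from depotflow import synthetic as S
from depotflow import transport as T


class TestRcsMap:
    def test_frame_equals_baseline_gives_zero(self):
        b = np.full((8, 8), 0.9)
        assert np.allclose(Q.rcs_map(b, b, 0.15), 0.0)

    def test_matches_chord_map_noiseless(self):
        """RCS of a rendered depot equals the analytic chord map within 2%."""
        scen = S.preset_scenario("slow-100", seed=1, noiseless=True, frame_shape=(128, 128), pixel_size_um=80)
        truth = S.simulate_depot(scen)
        i = len(truth.times_s) - 1
        gain, offset = scen.detector.fixed_patterns(scen.frame_shape, scen.seed)
        flat = I.FlatFieldSet(gain=gain + offset, offset=offset)
        base = I.flat_field_correct(S.render_projection(0, 0, scen), flat)
        frame = I.flat_field_correct(
            S.render_projection(truth.semi_axis_h_mm[i], truth.semi_axis_v_mm[i], scen), flat
        )
        rcs = Q.rcs_map(frame, base, scen.tissue.mu_abs_per_mm)
        chord = S.ellipsoid_chord_map(
            scen.frame_shape, scen.protocol.needle_tip,
            truth.semi_axis_h_mm[i], truth.semi_axis_v_mm[i], scen.pixel_size_um,
        )
        big = chord > 0.5
        assert np.allclose(rcs.data[big], chord[big], rtol=0.02)

    def test_pure_noise_median_near_zero(self):
        rng = np.random.default_rng(3)
        base = 0.9 * np.ones((64, 64))
        frame = base * (1 + 0.01 * rng.standard_normal((64, 64)))
        rcs = Q.rcs_map(frame, base, 0.15)
        # negatives are clipped, so the median sits at the noise floor scale
        assert np.ma.median(rcs) < 0.01 / 0.15

    def test_mask_propagates(self):
        b = np.ma.MaskedArray(np.ones((4, 4)), mask=np.zeros((4, 4), bool))
        b.mask[0, 0] = True
        out = Q.rcs_map(np.ones((4, 4)), b, 1.0)
        assert out.mask[0, 0]


class TestRcsProfile:
    def test_uniform_map_flat_profile(self):
        d, v = Q.rcs_profile(np.ones((60, 60)), (30, 30), "horizontal", pixel_size_um=100, window_mm=0.9)
        assert np.allclose(v, 1.0)

    def test_spherical_depot_monotone_nonincreasing(self):
        chord = S.ellipsoid_chord_map((100, 100), (50, 50), 3.0, 3.0, 80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d, v = Q.rcs_profile(chord, (50, 50), "horizontal", pixel_size_um=80)
        assert np.all(np.diff(v) <= 1e-12)

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            Q.rcs_profile(np.ones((5, 5)), (2, 2), "horizontal", pixel_size_um=9, window_mm=0.9)

    def test_needle_outside_rejected(self):
        with pytest.raises(ValueError):
            Q.rcs_profile(np.ones((50, 50)), (60, 10), "horizontal", pixel_size_um=100)

    def test_border_needle_warns(self):
        with pytest.warns(UserWarning):
            Q.rcs_profile(np.ones((60, 60)), (1, 1), "horizontal", pixel_size_um=100, window_mm=0.9)

    def test_series_normalized_to_global_max(self):
        maps = [np.full((60, 60), 0.5), np.full((60, 60), 1.0)]
        series = Q.build_rcs_series(maps, [0.0, 10.0], (30, 30), "horizontal", 100)
        assert series.values.max() == pytest.approx(1.0)
        assert series.values[0].max() == pytest.approx(0.5)


class TestRcsTemporalVariation:
    def test_identical_profiles_zero(self):
        p = np.linspace(1, 0, 10)
        assert np.allclose(Q.rcs_temporal_variation(p, p, 0, 5), 0.0)

    def test_linear_filling_constant_rate(self):
        p1 = np.zeros(5)
        p2 = np.full(5, 3.0)
        assert np.allclose(Q.rcs_temporal_variation(p1, p2, 0.0, 6.0), 0.5)

    def test_equal_times_rejected(self):
        with pytest.raises(ValueError):
            Q.rcs_temporal_variation(np.zeros(3), np.ones(3), 5.0, 5.0)

    def test_filling_sequence_nonnegative_inside_wf(self):
        """During infusion the RCS rate is nonnegative everywhere inside the
        front (the depot only accumulates solution)."""
        scen = S.preset_scenario("slow-100", seed=4, noiseless=True, frame_shape=(128, 128), pixel_size_um=80)
        truth = S.simulate_depot(scen)
        idx = [len(truth.times_s) // 2, len(truth.times_s) - 1]
        chords = [
            S.ellipsoid_chord_map((128, 128), (64, 64), truth.semi_axis_h_mm[i], truth.semi_axis_v_mm[i], 80)
            for i in idx
        ]
        profiles = [Q.rcs_profile(c, (64, 64), "horizontal", 80, normalize=False)[1] for c in chords]
        d = Q.rcs_profile(chords[0], (64, 64), "horizontal", 80, normalize=False)[0]
        rate = Q.rcs_temporal_variation(profiles[0], profiles[1], truth.times_s[idx[0]], truth.times_s[idx[1]])
        inside = d <= truth.semi_axis_h_mm[idx[0]]
        assert np.all(rate[inside] >= -1e-12)


class TestDetectWf:
    def test_step_profile(self):
        d = np.linspace(0, 10, 101)
        v = np.where(d <= 4.0, 1.0, 0.0)
        assert Q.detect_wf(d, v) == pytest.approx(4.0, abs=0.2)

    def test_all_zero_profile_no_front(self):
        assert Q.detect_wf(np.arange(5.0), np.zeros(5)) is None

    def test_ellipsoid_semi_axis_within_two_pixels(self):
        px = 80
        chord = S.ellipsoid_chord_map((128, 128), (64, 64), 3.0, 2.4, px)
        d, v = Q._line_profile(chord, (64, 64), "horizontal", px)
        wf = Q.detect_wf(d, v)
        assert abs(wf - 3.0) <= 2 * px * 1e-3


class TestTrackAndAspect:
    def test_isotropic_symmetry(self):
        """An isotropic depot yields |wf_h - wf_v| within 2 pixels throughout."""
        base = S.preset_scenario("slow-100", seed=6, noiseless=True)
        scen = S.ScenarioConfig(
            protocol=base.protocol,
            tissue=T.TissueParameters(anisotropy=1.0, lag_volume_ul=base.tissue.lag_volume_ul),
            frame_times_s=base.frame_times_s,
            frame_shape=base.frame_shape,
            pixel_size_um=base.pixel_size_um,
            seed=base.seed,
            noiseless=True,
        )
        from conftest import correct_stack

        corrected, truth, _ = correct_stack(scen)
        trace = Q.track_wf(corrected, scen.protocol, scen.tissue)
        fin = np.isfinite(trace.wf_h_mm) & np.isfinite(trace.wf_v_mm)
        px_mm = scen.pixel_size_um * 1e-3
        assert np.all(np.abs(trace.wf_h_mm[fin] - trace.wf_v_mm[fin]) <= 2 * px_mm)

    def test_wf_monotone_during_ir(self, slow100_noiseless):
        scen, corrected, truth, _ = slow100_noiseless
        trace = Q.track_wf(corrected, scen.protocol, scen.tissue)
        ir = trace.in_region("IR") & np.isfinite(trace.wf_h_mm)
        assert np.all(np.diff(trace.wf_h_mm[ir]) >= -1e-12)

    def test_cube_root_loglog_slope(self, slow100_noiseless):
        """IR WF growth follows the cube-root law: log-log slope 1/3 +/- 0.05."""
        scen, corrected, truth, manifest = slow100_noiseless
        trace = Q.track_wf(corrected, scen.protocol, scen.tissue)
        onset = manifest["onset_time_s"]
        ir = trace.in_region("IR") & np.isfinite(trace.wf_h_mm) & (trace.times_s > onset)
        t = trace.times_s[ir] - onset
        w = trace.wf_h_mm[ir]
        slope = np.polyfit(np.log(t[t > 0]), np.log(w[t > 0]), 1)[0]
        assert slope == pytest.approx(1 / 3, abs=0.05)

    def test_aspect_ratio_isotropic(self):
        trace = Q.WFTrace(
            times_s=np.arange(4.0),
            wf_h_mm=np.array([1.0, 2.0, 3.0, 4.0]),
            wf_v_mm=np.array([1.0, 2.0, 3.0, 4.0]),
            region=np.array(["IR"] * 4),
        )
        m, s = Q.aspect_ratio(trace, "IR")
        assert (m, s) == (1.0, 0.0)

    def test_aspect_ratio_recovers_generator_anisotropy(self, slow100_noiseless):
        scen, corrected, truth, manifest = slow100_noiseless
        trace = Q.track_wf(corrected, scen.protocol, scen.tissue)
        m, s = Q.aspect_ratio(trace, "IR")
        assert m == pytest.approx(manifest["anisotropy"], abs=0.05)

    def test_aspect_ratio_empty_region(self):
        trace = Q.WFTrace(
            times_s=np.array([0.0]), wf_h_mm=np.array([1.0]), wf_v_mm=np.array([1.0]),
            region=np.array(["IR"]),
        )
        with pytest.raises(ValueError):
            Q.aspect_ratio(trace, "DR")

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=25, derandomize=True)
    def test_aspect_ratio_scale_invariance(self, scale):
        wf_h = np.array([1.0, 2.0, 3.0])
        wf_v = np.array([0.8, 1.7, 2.2])
        base = Q.WFTrace(np.arange(3.0), wf_h, wf_v, np.array(["IR"] * 3))
        scaled = Q.WFTrace(np.arange(3.0), scale * wf_h, scale * wf_v, np.array(["IR"] * 3))
        assert Q.aspect_ratio(scaled, "IR")[0] == pytest.approx(Q.aspect_ratio(base, "IR")[0], rel=1e-12)


class TestTiming:
    def test_onset_lag_volume_over_flow(self, slow100_noisy):
        """Onset is detected at V_lag/q within one frame interval (60 s case)."""
        scen, corrected, truth, manifest = slow100_noisy
        r0, c0 = scen.protocol.needle_tip
        base = np.mean(corrected.frames[:1], axis=0)
        central = np.array(
            [
                float(np.ma.mean(Q.rcs_map(f, base, scen.tissue.mu_abs_per_mm)[r0 - 2 : r0 + 3, c0 - 2 : c0 + 3]))
                for f in corrected.frames
            ]
        )
        onset = Q.onset_time(corrected.timestamps, central)
        dt = float(np.diff(corrected.timestamps).mean())
        assert onset is not None
        assert abs(onset - manifest["onset_time_s"]) <= dt

    def test_zero_lag_onset_first_frame(self):
        t = np.arange(10.0)
        v = np.concatenate([np.zeros(3), np.ones(7)])
        assert Q.onset_time(t, v) == 3.0

    def test_onset_never_exceeded(self):
        assert Q.onset_time(np.arange(10.0), np.zeros(10)) is None

    def test_qs_constant_trace(self):
        t = np.arange(0, 200, 10.0)
        assert Q.quasi_saturation_time(t, np.full(t.size, 3.0)) == 0.0

    def test_qs_never_met_for_growing_cube_root(self):
        t = np.arange(1, 300, 10.0)
        w = t ** (1 / 3)
        assert Q.quasi_saturation_time(t, w, rel_tol=0.01, window_s=60) is None

    def test_qs_detects_plateau(self):
        t = np.arange(0, 400, 10.0)
        w = np.minimum(t / 120.0, 1.0) * 4.0  # plateau at 2 min
        qs = Q.quasi_saturation_time(t, w, rel_tol=0.01, window_s=60)
        assert qs is not None
        assert abs(qs - 120.0) <= 60.0


class TestRoi:
    def _stack(self, frames):
        return I.ImageStack(np.asarray(frames, dtype=float), np.arange(len(frames), dtype=float), 9.0)

    def test_constant_roi_zero_cv(self):
        stats = Q.roi_cv(self._stack([np.full((6, 6), 5.0)]), (0, 6, 0, 6))
        assert stats.cv[0] == 0.0

    def test_two_value_roi(self):
        frame = np.ones((2, 2))
        frame[:, 1] = 3.0
        stats = Q.roi_cv(self._stack([frame]), (0, 2, 0, 2))
        assert stats.cv[0] == pytest.approx(0.5)  # population sigma

    def test_zero_mean_undefined(self):
        stats = Q.roi_cv(self._stack([np.zeros((4, 4))]), (0, 4, 0, 4))
        assert np.isnan(stats.cv[0])

    def test_cv_decreases_during_filling(self, slow100_noiseless):
        """At the front ROIs, C_v falls as the depot fills past them."""
        scen, corrected, truth, _ = slow100_noiseless
        trace = Q.track_wf(corrected, scen.protocol, scen.tissue)
        rois = Q.define_rois(scen.protocol.needle_tip, trace, corrected.pixel_size_um, corrected.shape)
        stats = Q.roi_cv(corrected, rois["SWF_h"])
        post = corrected.timestamps >= trace.times_s[np.isfinite(trace.wf_h_mm)][0]
        cv = stats.cv[post]
        assert cv[-1] <= cv[0] + 1e-9

    def test_define_rois_geometry(self):
        trace = Q.WFTrace(
            times_s=np.array([0.0, 10.0]),
            wf_h_mm=np.array([np.nan, 1.0]),
            wf_v_mm=np.array([np.nan, 1.0]),
            region=np.array(["IR", "IR"]),
        )
        rois = Q.define_rois((120, 120), trace, pixel_size_um=9.0, frame_shape=(320, 320))
        sc = rois["SC"]
        # SC centred at the needle; boxes are 0.9 mm / 9 um = 100 px square
        assert sc == (70, 170, 70, 170)
        assert rois["SWF_h"][2] == 70 + round(1.0 / 0.009)
        for r0, r1, c0, c1 in rois.values():
            assert r1 > r0 and c1 > c0

    def test_define_rois_clipped_with_warning(self):
        trace = Q.WFTrace(
            times_s=np.array([0.0]), wf_h_mm=np.array([1.0]), wf_v_mm=np.array([1.0]),
            region=np.array(["IR"]),
        )
        with pytest.warns(UserWarning):
            rois = Q.define_rois((5, 5), trace, pixel_size_um=9.0, frame_shape=(120, 120))
        assert rois["SC"][0] == 0

    def test_mass_monotone_during_ir(self, slow100_noiseless):
        """Total RCS over the frame is nondecreasing while solution is injected."""
        scen, corrected, truth, _ = slow100_noiseless
        base = corrected.frames[0]
        totals = [
            float(np.ma.sum(Q.rcs_map(f, base, scen.tissue.mu_abs_per_mm)))
            for f in corrected.frames
        ]
        assert np.all(np.diff(totals) >= -1e-9)
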