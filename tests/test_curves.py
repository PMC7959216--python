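"""Curve resampling, landmark detection and feature extraction."""

import dataclasses

import numpy as np
import pytest

from fontanstress import (
    AtrialFeatures,
    VentricularFeatures,
    VolumeTimeCurve,
    compute_reserve,
    deceleration_time,
    detect_landmarks,
    extract_features,
    generate_cycle,
    haycock_bsa,
    index_features,
    resample_periodic,
)
from fontanstress.synthetic import physiological_grid

from conftest import make_params


def _curve(volumes, T=800.0, chamber="ventricle", condition="rest"):
    n = len(volumes)
    return VolumeTimeCurve(
        times=np.arange(n) * T / n,
        volumes=np.asarray(volumes, dtype=float),
        chamber=chamber,
        condition=condition,
        heart_rate=60000.0 / T,
        cycle_ms=T,
    )


class TestVolumeTimeCurve:
    def test_validation_errors(self):
        good = np.full(30, 80.0)
        with pytest.raises(ValueError, match=">= 16 samples"):
            _curve(good[:10])
        with pytest.raises(ValueError, match="> 0"):
            _curve(np.concatenate([good[:-1], [-1.0]]))
        with pytest.raises(ValueError, match="start at 0"):
            VolumeTimeCurve(np.arange(1, 31) * 10.0, good, "ventricle", "rest", 75.0)
        with pytest.raises(ValueError, match="heart rate"):
            VolumeTimeCurve(np.arange(30) * 10.0, good, "ventricle", "rest", 120.0)


class TestResample:
    def test_constant_curve(self):
        out = resample_periodic(_curve(np.full(30, 80.0)), 100)
        assert np.allclose(out.volumes, 80.0, atol=1e-8)

    def test_sinusoid_against_analytic(self):
        # periodic spline through 30 samples must track the sinusoid to
        # well under 0.5% of its amplitude
        T, amp = 800.0, 20.0
        t30 = np.arange(30) * T / 30
        curve = _curve(100.0 + amp * np.sin(2 * np.pi * t30 / T))
        out = resample_periodic(curve, 300)
        truth = 100.0 + amp * np.sin(2 * np.pi * out.times / T)
        assert np.max(np.abs(out.volumes - truth)) < 0.005 * amp

    def test_reproduces_original_samples(self):
        rng = np.random.default_rng(7)
        vols = 80.0 + np.cumsum(rng.normal(0, 0.5, 30))
        vols -= np.linspace(0, vols[-1] - vols[0], 30)  # keep roughly periodic
        vols = np.abs(vols) + 10.0
        curve = _curve(vols)
        out = resample_periodic(curve, 30)
        assert np.allclose(out.volumes, curve.volumes, atol=1e-8)

    def test_resample_then_edv_matches_ground_truth(self):
        params = make_params()
        vc, _, gt = generate_cycle(params, n_frames=30)
        dense = resample_periodic(vc, 512)
        assert abs(dense.volumes.max() - gt.edv) < 0.5

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError):
            resample_periodic(_curve(np.full(30, 80.0)), 8)


class TestLandmarks:
    def test_a_onset_within_one_frame_of_generative_onset(self):
        params = make_params(systole_fraction=0.45)
        vc, ac, gt = generate_cycle(params, n_frames=30)
        lm = detect_landmarks(vc, ac)
        T = vc.cycle_ms
        ts = params.systole_fraction * T
        nominal = ts + 0.7 * (T - ts)
        assert abs(lm.t_a_onset - nominal) <= T / 30
        assert abs(lm.t_a_onset - gt.t_a_onset) <= T / 30
        assert not lm.fusion

    def test_absent_a_wave_triggers_fusion_fallback(self):
        params = make_params(a_fill_volume=0.0)
        vc, ac, _ = generate_cycle(params, n_frames=30)
        lm = detect_landmarks(vc, ac)
        assert lm.fusion
        assert "ea_fusion_fallback_onset" in lm.flags
        expected = lm.diastole_start + 2.0 / 3.0 * lm.diastole_duration
        assert abs(lm.t_a_onset - expected) < 1e-6

    def test_single_minimum_vee_curve(self):
        T = 800.0
        t = np.arange(32) * T / 32
        v = 100.0 - 40.0 * np.sin(np.pi * t / T) ** 2  # single min at T/2
        a = np.full(32, 50.0)
        lm = detect_landmarks(_curve(v, T), _curve(a, T, chamber="atrium"))
        assert abs(lm.t_es - T / 2) < T / 32

    def test_mismatched_cycle_durations_rejected(self):
        vc = _curve(np.full(30, 80.0), T=800.0)
        ac = _curve(np.full(30, 50.0), T=900.0, chamber="atrium")
        with pytest.raises(ValueError, match="do not overlap"):
            detect_landmarks(vc, ac)


class TestVentricularExtraction:
    @pytest.mark.parametrize("case", [0, 107, 215, 323, 431])
    def test_recovery_against_generator_truth(self, case):
        params = physiological_grid()[case]
        vc, ac, gt = generate_cycle(params, n_frames=30)
        vf, af, _ = extract_features(vc, ac)
        assert abs(vf.edv - gt.edv) < 0.5
        assert abs(vf.esv - gt.esv) < 0.5
        assert abs(vf.sv - gt.sv) < 0.5
        assert vf.early_filling_volume == pytest.approx(gt.early_filling_volume, rel=0.02)
        assert vf.late_filling_volume == pytest.approx(gt.late_filling_volume, rel=0.02)
        assert vf.early_peak_filling_rate == pytest.approx(
            gt.early_peak_filling_rate, rel=0.02
        )
        assert vf.late_peak_filling_rate == pytest.approx(
            gt.late_peak_filling_rate, rel=0.02
        )
        assert vf.deceleration_time == pytest.approx(gt.deceleration_time, rel=0.05)
        assert vf.e_a_ratio == pytest.approx(gt.e_a_ratio, rel=0.04)

    def test_peak_rate_closed_form(self):
        # a raised-cosine E lobe of volume q and width w peaks at 2q/w
        params = make_params(e_fill_volume=35.0, a_fill_volume=15.0)
        vc, ac, _ = generate_cycle(params, n_frames=45)
        vf, _, _ = extract_features(vc, ac)
        D = (1 - params.systole_fraction) * params.cycle_ms
        expected = 2.0 * 35.0 / (params.e_width_frac * D / 1000.0)
        assert vf.early_peak_filling_rate == pytest.approx(expected, rel=0.02)

    def test_flat_curve_all_zero(self):
        vc = _curve(np.full(30, 80.0))
        ac = _curve(np.full(30, 50.0), chamber="atrium")
        vf, af, lm = extract_features(vc, ac)
        assert "flat_ventricular_curve" in lm.flags
        assert vf.sv == pytest.approx(0.0, abs=1e-9)
        assert vf.early_filling_volume == pytest.approx(0.0, abs=1e-9)
        assert vf.late_filling_volume == pytest.approx(0.0, abs=1e-9)
        assert vf.early_peak_filling_rate == 0.0
        assert vf.late_peak_filling_rate == 0.0
        assert np.isnan(vf.e_a_ratio)
        assert np.isnan(vf.deceleration_time)
        assert af.cyclic_volume_change == pytest.approx(0.0, abs=1e-9)
        assert af.early_emptying_volume == pytest.approx(0.0, abs=1e-9)
        assert af.late_emptying_volume == pytest.approx(0.0, abs=1e-9)
        assert af.conduit_volume == pytest.approx(vf.sv, abs=1e-9)

    def test_rotation_invariance(self):
        params = make_params()
        vc, ac, _ = generate_cycle(params, n_frames=30)
        ref, _, _ = extract_features(vc, ac)
        shift = 10
        vc2 = dataclasses.replace(vc, volumes=np.roll(vc.volumes, shift))
        ac2 = dataclasses.replace(ac, volumes=np.roll(ac.volumes, shift))
        rot, _, _ = extract_features(vc2, ac2)
        assert rot.edv == pytest.approx(ref.edv, abs=0.2)
        assert rot.sv == pytest.approx(ref.sv, abs=0.4)
        assert rot.early_filling_volume == pytest.approx(
            ref.early_filling_volume, rel=0.02
        )
        assert rot.early_peak_filling_rate == pytest.approx(
            ref.early_peak_filling_rate, rel=0.02
        )

    def test_errors_shrink_with_frame_count(self):
        params = make_params()
        errs = []
        for n in (16, 30, 60):
            vc, ac, gt = generate_cycle(params, n_frames=n)
            vf, _, _ = extract_features(vc, ac)
            errs.append(
                max(
                    abs(vf.edv - gt.edv),
                    abs(vf.esv - gt.esv),
                    abs(vf.early_filling_volume - gt.early_filling_volume),
                )
            )
        assert errs[0] >= errs[1] >= errs[2] - 1e-9


class TestDecelerationTime:
    def test_exact_linear_decay(self):
        # rate falling linearly 200 -> 0 over 160 ms extrapolates to DT=160
        t = np.linspace(0.0, 160.0, 33)
        r = 200.0 * (1 - t / 160.0)
        dt, flags = deceleration_time(t, r, t_e_peak=0.0)
        assert dt == pytest.approx(160.0, abs=1e-6)
        assert flags == ()

    def test_insufficient_band_support_flagged(self):
        t = np.array([0.0, 50.0, 100.0, 150.0])
        r = np.array([200.0, 120.0, 30.0, 0.0])  # only 2 samples in 70-30% band
        dt, flags = deceleration_time(t, r, t_e_peak=0.0)
        assert np.isnan(dt)
        assert "dt_insufficient_support" in flags

    def test_nonnegative_slope_flagged(self):
        t = np.linspace(0.0, 100.0, 20)
        r = np.concatenate([[200.0], np.full(19, 100.0)])
        dt, flags = deceleration_time(t, r, t_e_peak=0.0)
        assert np.isnan(dt)
        assert "dt_nonnegative_slope" in flags

    def test_hann_limb_matches_closed_form_truth(self):
        params = make_params()
        vc, ac, gt = generate_cycle(params, n_frames=30)
        vf, _, _ = extract_features(vc, ac)
        assert vf.deceleration_time == pytest.approx(gt.deceleration_time, rel=0.05)


class TestAtrialExtraction:
    def test_constant_atrial_curve(self):
        params = make_params()
        vc, _, _ = generate_cycle(params, n_frames=30)
        ac = _curve(np.full(30, 48.0), T=vc.cycle_ms, chamber="atrium")
        vf, af, _ = extract_features(vc, ac)
        assert af.cyclic_volume_change == pytest.approx(0.0, abs=1e-9)
        assert af.early_emptying_volume == pytest.approx(0.0, abs=1e-9)
        assert af.late_emptying_volume == pytest.approx(0.0, abs=1e-9)
        assert af.conduit_volume == pytest.approx(vf.sv, abs=1e-9)

    @pytest.mark.parametrize("case", [0, 150, 300, 431])
    def test_recovery_and_conduit_identity(self, case):
        params = physiological_grid()[case]
        vc, ac, gt = generate_cycle(params, n_frames=30)
        vf, af, _ = extract_features(vc, ac)
        assert af.v_max == pytest.approx(gt.v_max, abs=0.5)
        assert af.v_min == pytest.approx(gt.v_min, abs=0.5)
        assert af.early_emptying_volume == pytest.approx(
            gt.early_emptying_volume, rel=0.02
        )
        assert af.late_emptying_volume == pytest.approx(
            gt.late_emptying_volume, rel=0.02
        )
        # exact identities, not approximate recovery
        assert af.cyclic_volume_change == af.v_max - af.v_min
        assert af.conduit_volume == pytest.approx(
            vf.sv - af.early_emptying_volume - af.late_emptying_volume, abs=1e-9
        )

    def test_missing_stroke_volume_rejected(self):
        params = make_params()
        vc, ac, _ = generate_cycle(params, n_frames=30)
        lm = detect_landmarks(vc, ac)
        from fontanstress import extract_atrial

        with pytest.raises(ValueError, match="stroke volume"):
            extract_atrial(ac, lm, float("nan"))


class TestHaycockAndIndexing:
    def test_haycock_reference_value(self):
        assert haycock_bsa(170.0, 70.0) == pytest.approx(1.8257, abs=5e-4)

    def test_haycock_weight_exponent(self):
        ratio = haycock_bsa(170.0, 140.0) / haycock_bsa(170.0, 70.0)
        assert ratio == pytest.approx(2.0**0.5378, rel=1e-12)

    def test_haycock_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            haycock_bsa(0.0, 70.0)
        with pytest.raises(ValueError):
            haycock_bsa(170.0, -1.0)

    def _features(self):
        return VentricularFeatures(
            edv=100.0, esv=50.0, sv=50.0, ef=50.0,
            early_filling_volume=35.0, late_filling_volume=15.0,
            early_peak_filling_rate=200.0, late_peak_filling_rate=100.0,
            e_a_ratio=2.0, deceleration_time=150.0,
        )

    def test_unit_bsa_is_identity(self):
        f = self._features()
        assert index_features(f, 1.0) == f

    def test_division_and_ratio_invariance(self):
        f = index_features(self._features(), 1.34)
        assert f.edv == pytest.approx(100.0 / 1.34)
        assert f.e_a_ratio == 2.0
        assert f.early_peak_filling_rate == 200.0
        assert f.deceleration_time == 150.0

    def test_round_trip_exact(self):
        f = self._features()
        back = index_features(index_features(f, 1.34), 1.0 / 1.34)
        for name in VentricularFeatures._volume_fields:
            assert getattr(back, name) == pytest.approx(getattr(f, name), rel=1e-12)

    def test_nonpositive_bsa_rejected(self):
        with pytest.raises(ValueError):
            index_features(self._features(), 0.0)


class TestReserve:
    def _pair(self):
        rest = VentricularFeatures(
            edv=96.8, esv=49.3, sv=47.5, ef=49.1,
            early_filling_volume=13.6, late_filling_volume=9.8,
            early_peak_filling_rate=194.0, late_peak_filling_rate=134.0,
            e_a_ratio=1.5, deceleration_time=177.0,
        )
        stress = dataclasses.replace(
            rest, edv=88.4, esv=38.1, sv=50.3, deceleration_time=float("nan")
        )
        return rest, stress

    def test_stress_equal_rest_gives_zero(self):
        rest, _ = self._pair()
        res = compute_reserve(rest, rest)
        assert res.edv == 0.0 and res.sv == 0.0 and res.e_a_ratio == 0.0

    def test_direct_subtraction(self):
        rest, stress = self._pair()
        res = compute_reserve(rest, stress)
        assert res.edv == pytest.approx(-8.4)
        assert res.esv == pytest.approx(-11.2)

    def test_missing_value_propagates_and_is_flagged(self):
        rest, stress = self._pair()
        res = compute_reserve(rest, stress)
        assert np.isnan(res.deceleration_time)
        assert any("deceleration_time" in f for f in res.flags)
        assert np.isfinite(res.edv)

    def test_schema_mismatch_rejected(self):
        rest, _ = self._pair()
        atrial = AtrialFeatures(40.0, 25.0, 15.0, 8.0, 6.0, 33.5)
        with pytest.raises(TypeError, match="schema mismatch"):
            compute_reserve(rest, atrial)
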