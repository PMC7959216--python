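"""Generator invariants: mass balance, ground truth, cohorts, reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import fontanstress as fs
from fontanstress.synthetic import hann_cdf, hann_rate

from conftest import make_params


class TestCycleParams:
    @pytest.mark.parametrize(
        "overrides, message",
        [
            (dict(edv=50.0, esv=60.0), "edv > esv"),
            (dict(e_fill_volume=40.0, a_fill_volume=40.0), "balances stroke volume"),
            (dict(systole_fraction=1.2), "systole_fraction"),
            (dict(a_onset_frac=0.3), "must not overlap"),
            (dict(a_onset_frac=0.9, a_width_frac=0.3), "A pulse window"),
            (dict(heart_rate=-5.0), "heart_rate"),
        ],
    )
    def test_invariant_violations_are_named(self, overrides, message):
        base = dataclasses.asdict(make_params())
        base.update(overrides)
        if "e_fill_volume" not in overrides:
            base["e_fill_volume"] = base["edv"] - base["esv"] - base["a_fill_volume"]
        base["venous_return_rate"] = (
            (base["edv"] - base["esv"]) * base["heart_rate"] / 60.0
        )
        with pytest.raises(ValueError, match=message):
            fs.CyclePhysioParams(**base).validate()

    def test_broken_mass_balance_is_named(self):
        params = dataclasses.replace(make_params(), venous_return_rate=99.0)
        with pytest.raises(ValueError, match="closed-loop mass balance"):
            params.validate()


class TestGenerateCycle:
    def test_trivial_mass_balance(self):
        # edv=100, esv=50, e=35, a=15, noiseless
        vc, ac, gt = fs.generate_cycle(make_params(), n_frames=60)
        assert vc.volumes[0] == pytest.approx(100.0)
        assert vc.volumes.max() == pytest.approx(100.0, abs=0.05)
        assert vc.volumes.min() == pytest.approx(50.0, abs=0.05)
        assert gt.sv == 50.0

    def test_periodicity_of_both_chambers(self):
        # dense noiseless cycles close on themselves: the ventricle returns to
        # EDV, and the atrium returns to its start once the venous return over
        # the final frame (its only inflow there) is accounted for
        params = make_params()
        vc, ac, _ = fs.generate_cycle(params, n_frames=600)
        dt = vc.cycle_ms / 600
        assert vc.volumes[-1] == pytest.approx(vc.volumes[0], abs=0.05)
        vr = params.venous_return_rate / 1000.0
        assert ac.volumes[-1] + vr * dt == pytest.approx(ac.volumes[0], abs=0.01)

    def test_degenerate_a_wave(self):
        _, _, gt = fs.generate_cycle(make_params(a_fill_volume=0.0), n_frames=30)
        assert gt.late_filling_volume == 0.0
        assert gt.late_emptying_volume == 0.0
        assert gt.fusion
        assert np.isnan(gt.e_a_ratio)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="n_frames"):
            fs.generate_cycle(make_params(), n_frames=8)
        with pytest.raises(ValueError, match="noise_sd"):
            fs.generate_cycle(make_params(), noise_sd=-1.0)

    def test_noise_is_seeded(self):
        a = fs.generate_cycle(make_params(), noise_sd=1.0, seed=5)[0]
        b = fs.generate_cycle(make_params(), noise_sd=1.0, seed=5)[0]
        c = fs.generate_cycle(make_params(), noise_sd=1.0, seed=6)[0]
        assert np.array_equal(a.volumes, b.volumes)
        assert not np.array_equal(a.volumes, c.volumes)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        edv=st.floats(70, 180),
        ef=st.floats(35, 65),
        efrac=st.floats(0.45, 0.9),
        hr=st.floats(55, 110),
        sf=st.floats(0.3, 0.5),
    )
    def test_ground_truth_identities_hold_for_all_valid_params(
        self, edv, ef, efrac, hr, sf
    ):
        sv = edv * ef / 100.0
        params = fs.CyclePhysioParams.closed_loop(
            edv=edv,
            esv=edv - sv,
            e_fill_volume=efrac * sv,
            a_fill_volume=(1 - efrac) * sv,
            systole_fraction=sf,
            e_peak_time_frac=0.2,
            e_width_frac=0.4,
            a_onset_frac=0.7,
            a_width_frac=0.3,
            heart_rate=hr,
            a_min_volume=25.0,
        )
        gt = fs.ground_truth(params)
        # conduit identity and cyclic identity hold to machine tolerance
        assert gt.conduit_volume == pytest.approx(
            gt.sv - gt.early_emptying_volume - gt.late_emptying_volume, abs=1e-9
        )
        assert gt.cyclic_volume_change == pytest.approx(
            gt.v_max - gt.v_min, abs=1e-12
        )
        assert gt.v_min == pytest.approx(25.0, abs=1e-9)
        assert gt.ef == pytest.approx(ef, rel=1e-9)


class TestConduitQuadratureOracle:
    def test_ground_truth_matches_independent_quadrature(self):
        # independent oracle: trapezoid quadrature of the generative flows
        # with crossing-based anchors, then the conduit formula
        params = make_params()  # edv 100, esv 50, e 35, a 15, E [0,0.4], A [0.7,1]
        T = params.cycle_ms
        ts = params.systole_fraction * T
        D = T - ts
        t = np.linspace(0.0, T, 200001)
        inflow = hann_rate(t, ts, 0.4 * D, 35.0) + hann_rate(t, ts + 0.7 * D, 0.3 * D, 15.0)
        vr = params.venous_return_rate / 1000.0
        va = np.concatenate(
            [[0.0], np.cumsum((vr - inflow)[:-1] + (vr - inflow)[1:]) / 2 * (t[1] - t[0])]
        )
        # anchors: last crossing where the A upstroke overtakes venous return
        a0 = ts + 0.7 * D
        in_a_up = (t >= a0) & (t <= a0 + 0.15 * D)
        i_on = np.nonzero(in_a_up & (inflow >= vr))[0][0]
        i_emax = np.argmax(va[: i_on])
        early = va[i_emax] - va[i_on]
        late = va[i_on] - va.min()
        conduit = 50.0 - early - late
        gt = fs.ground_truth(params)
        assert gt.early_emptying_volume == pytest.approx(early, rel=1e-3)
        assert gt.late_emptying_volume == pytest.approx(late, rel=1e-3)
        assert gt.conduit_volume == pytest.approx(conduit, rel=1e-3)
        # and extraction on the noiseless curve agrees with the oracle
        vc, ac, _ = fs.generate_cycle(params, n_frames=30)
        _, af, _ = fs.extract_features(vc, ac)
        assert af.conduit_volume == pytest.approx(conduit, rel=0.02)


class TestCohort:
    def test_group_sizes_match_config(self):
        study = fs.generate_cohort(fs.CohortConfig(seed=0))
        counts = study.cohort["modification"].value_counts()
        assert len(study.cohort) == 57
        assert counts["ECC"] == 26
        assert counts["ILT"] == 31

    def test_seeded_reproducibility_bit_for_bit(self):
        cfg = fs.CohortConfig(n_patients=8, n_ecc=4, n_ilt=4, seed=11)
        s1 = fs.generate_cohort(cfg)
        s2 = fs.generate_cohort(cfg)
        pd.testing.assert_frame_equal(s1.cohort, s2.cohort)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        pd.testing.assert_frame_equal(s1.events, s2.events)
        assert s1.curves_frame().to_csv() == s2.curves_frame().to_csv()

    def test_different_seed_differs(self):
        cfg = fs.CohortConfig(n_patients=8, n_ecc=4, n_ilt=4, seed=11)
        cfg2 = dataclasses.replace(cfg, seed=12)
        assert not fs.generate_cohort(cfg).cohort.equals(fs.generate_cohort(cfg2).cohort)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_ecc"):
            fs.CohortConfig(n_patients=10, n_ecc=4, n_ilt=4).validate()
        with pytest.raises(ValueError, match="unachievable correlation"):
            fs.CohortConfig(
                outcome=fs.OutcomeConfig(spearman_rho=1.5)
            ).validate()
        with pytest.raises(ValueError, match="n_frames"):
            fs.CohortConfig(n_frames=8).validate()

    def test_copula_hits_target_rank_correlation(self):
        # large-n Monte-Carlo check of the Gaussian-copula construction
        cfg = fs.CohortConfig(
            n_patients=500,
            n_ecc=250,
            n_ilt=250,
            noise_sd=0.0,
            n_frames=16,
            seed=42,
            outcome=fs.OutcomeConfig(
                correlated_feature="a_early_empty", spearman_rho=0.66, stratum=None
            ),
        )
        study = fs.generate_cohort(cfg)
        rho = spearmanr(
            study.cohort["a_early_empty_reserve"], study.cohort["peak_vo2"]
        ).statistic
        assert rho == pytest.approx(0.66, abs=0.05)

    def test_truth_table_conduit_identity(self):
        study = fs.generate_cohort(fs.CohortConfig(n_patients=8, n_ecc=4, n_ilt=4))
        resid = study.truth["a_conduit"] - (
            study.truth["sv"]
            - study.truth["a_early_empty"]
            - study.truth["a_late_empty"]
        )
        assert np.max(np.abs(resid)) < 1e-9

    def test_events_consistent_with_records(self):
        study = fs.generate_cohort(fs.CohortConfig(seed=2))
        c = study.cohort
        with_event = c[c["event"]]
        assert (with_event["time_days"] <= with_event["followup_days"]).all()
        # every event time corresponds to a qualifying record
        for _, row in with_event.iterrows():
            recs = study.events[study.events["patient_id"] == row["patient_id"]]
            qual = recs[recs["qualifying"] == 1]
            assert row["time_days"] == qual["offset_days"].min()


class TestCpetSeries:
    def test_noiseless_plateau_mean_is_exact(self):
        series = fs.generate_cpet_series(peak_vo2=40.0, rer_max=1.12)
        final = series[series["time_s"] >= series["time_s"].max() - 30.0]
        assert final["vo2"].mean() == pytest.approx(40.0, abs=1e-9)

    def test_submaximal_rer_excludes_subject_downstream(self):
        series = fs.generate_cpet_series(peak_vo2=40.0, rer_max=1.04)
        res = fs.process_cpet(series)
        assert not res.maximal_effort
        assert np.isnan(res.peak_vo2)

    def test_configured_slope_is_recovered(self):
        series = fs.generate_cpet_series(peak_vo2=35.0, rer_max=1.15, ve_vco2_slope=29.5)
        res = fs.process_cpet(series)
        assert res.ve_vco2_slope == pytest.approx(29.5, abs=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            fs.generate_cpet_series(peak_vo2=40.0, rer_max=1.1, duration_s=30.0)


class TestSimulateSurvival:
    def test_shape_and_censoring(self):
        df = fs.simulate_survival(100, 0.1, censor_years=5.0, seed=1)
        assert len(df) == 100
        assert df["time_years"].max() <= 5.0
        assert df.loc[~df["event"], "time_years"].eq(5.0).all()

    def test_hann_pulse_primitives(self):
        t = np.linspace(-1.0, 2.0, 2001)
        r = hann_rate(t, 0.0, 1.0, 10.0)
        assert np.trapezoid(r, t) == pytest.approx(10.0, abs=1e-4)
        assert r[t < 0].sum() == 0.0 and r[t > 1].sum() == 0.0
        assert hann_cdf(np.array([2.0]), 0.0, 1.0, 10.0)[0] == pytest.approx(10.0)
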