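import numpy as np
import pytest
from scipy.optimize import brentq

from respmon.gridding import TrainingStats, build_grid, impute
from respmon.oxygenation import (
    AMBIENT_FIO2,
    SOURCE_FORWARD_FILL,
    SOURCE_MEASURED,
    SOURCE_MODEL,
    EllisEstimator,
    OxygenationState,
    PaO2Estimator,
    ellis_pao2,
    estimate_fio2_track,
    estimate_pao2_track,
    pao2_feature_vector,
    pao2_sample_weight,
    pf_track,
    severinghaus,
    smooth_spo2,
)
from respmon.pipeline import fit_pao2_estimator_on_cohort, process_stay
from respmon.schema import MODE_NIV, default_schema
from respmon.simulate import SimConfig, simulate_cohort

from conftest import make_stay


class TestDissociationCurve:
    def test_round_trip_against_root_finder(self):
        # independent oracle: invert the forward curve numerically
        for s in (0.6, 0.8, 0.9, 0.95, 0.97747, 0.99):
            p_oracle = brentq(lambda p: severinghaus(p) - s, 1.0, 800.0, xtol=1e-10)
            assert ellis_pao2(s) == pytest.approx(p_oracle, abs=1e-6)

    def test_known_point_100_mmhg(self):
        s = float(severinghaus(100.0))
        assert s == pytest.approx(0.97747, abs=5e-5)
        assert ellis_pao2(s) == pytest.approx(100.0, abs=1e-6)

    def test_round_trip_error_below_1e6_over_range(self):
        s = np.linspace(0.5, 0.999, 2000)
        back = severinghaus(ellis_pao2(s))
        assert np.max(np.abs(back - s)) < 1e-6

    def test_half_saturation_point(self):
        p50 = ellis_pao2(0.5)
        assert severinghaus(p50) == pytest.approx(0.5, abs=1e-9)
        assert 20.0 < p50 < 30.0  # physiological P50

    def test_monotone(self):
        s = np.linspace(0.5, 0.99, 100)
        assert np.all(np.diff(ellis_pao2(s)) > 0)

    def test_saturation_clamped_above_one(self):
        assert ellis_pao2(1.0) == pytest.approx(ellis_pao2(0.9995))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ellis_pao2(0.0)


class TestSmoothSpo2:
    def test_constant_series(self):
        x = np.full(50, 97.0)
        assert np.allclose(smooth_spo2(x), 97.0)

    def test_window_percentile_brute_force(self):
        # a window containing {90, 96, 97, 98} has 75th percentile 97.25
        x = np.full(7, np.nan)
        x[1], x[3], x[4], x[5] = 90.0, 96.0, 97.0, 98.0
        out = smooth_spo2(x)
        assert out[3] == pytest.approx(np.percentile([90, 96, 97, 98], 75)) == 97.25

    def test_single_value_in_window(self):
        x = np.full(20, np.nan)
        x[10] = 93.0
        out = smooth_spo2(x)
        assert out[10] == 93.0

    def test_missing_window_propagates(self):
        x = np.full(30, np.nan)
        x[0] = 95.0
        assert np.isnan(smooth_spo2(x)[20])


class TestSampleWeight:
    def test_midpoint_110_gives_60(self):
        assert pao2_sample_weight(110.0) == pytest.approx(60.0)

    def test_high_pao2_limit_is_10(self):
        assert pao2_sample_weight(1e6) == pytest.approx(10.0)

    def test_70_mmhg(self):
        assert pao2_sample_weight(70.0) == pytest.approx(10 + 100 / (1 + np.exp(-1)), abs=1e-9)
        assert pao2_sample_weight(70.0) == pytest.approx(83.1, abs=0.1)


class TestFeatureVector:
    def _state(self, base=None):
        b = base if base is not None else [97, 90, 96, 7.4, 5, 60, 96.5]
        return OxygenationState(*b)

    def test_120_monomials(self):
        from math import comb

        v = pao2_feature_vector(self._state())
        assert len(v) == comb(7 + 3, 3) == 120

    def test_zero_vector_only_bias(self):
        v = pao2_feature_vector(self._state([0] * 7))
        assert v[0] == 1.0 and np.all(v[1:] == 0.0)

    def test_deterministic_order(self):
        a = pao2_feature_vector(self._state())
        b = pao2_feature_vector(self._state())
        assert np.array_equal(a, b)

    def test_prior_error_padding(self):
        st = self._state()
        st.prior_errors = [1.0, 2.0]
        padded = st.padded_errors()
        assert len(padded) == 10
        assert np.array_equal(padded[-2:], [1.0, 2.0]) and np.all(padded[:-2] == 0)


@pytest.fixture(scope="module")
def ph_shift_cohort():
    cfg = SimConfig(n_stays=60, seed=5, ph_sick_drop=0.22, ph_sigma=0.01)
    return simulate_cohort(cfg)[0]


class TestPaO2Estimator:
    def test_refuses_tiny_training_set(self, schema, small_stats):
        est = PaO2Estimator()
        g = impute(
            build_grid(make_stay({"pao2": [(0, 90.0)], "sao2": [(0, 97.0)], "ph": [(0, 7.4)],
                                  "spo2": [(0, 97.0)]}, n_bins=20), schema),
            schema, "dense", small_stats,
        )
        with pytest.raises(ValueError, match="refusing"):
            est.fit([g], [g])

    def test_beats_ellis_on_ph_shifted_cohort(self, schema, ph_shift_cohort):
        stays = ph_shift_cohort
        stats = TrainingStats.fit(stays[:40], schema)
        est = fit_pao2_estimator_on_cohort(stays[:40], stays[40:50], schema, stats)
        from respmon.oxygenation import _measurement_context

        ell = EllisEstimator()
        se_m, se_e = [], []
        for s in stays[50:]:
            g = impute(build_grid(s, schema), schema, "dense", stats)
            base, y, _, ok = _measurement_context(g)
            if not ok.any():
                continue
            E = PaO2Estimator._prior_error_matrix(
                y[ok] - est.predict_base(base[ok]), np.zeros(ok.sum())
            )
            se_m.append((est.predict(base[ok], E) - y[ok]) ** 2)
            se_e.append((ell.predict_from_spo2(base[ok, 0]) - y[ok]) ** 2)
        rmse_m = np.sqrt(np.mean(np.concatenate(se_m)))
        rmse_e = np.sqrt(np.mean(np.concatenate(se_e)))
        assert rmse_m <= rmse_e + 1e-9

    def test_constant_cohort_predicts_constant(self, schema, small_stats):
        rng = np.random.default_rng(0)
        grids = []
        for i in range(6):
            obs = {
                "spo2": [(float(m), 96.0) for m in range(0, 1200, 5)],
                "pao2": [(float(m), 88.0) for m in range(0, 1200, 60)],
                "sao2": [(float(m), 96.0) for m in range(0, 1200, 60)],
                "ph": [(float(m), 7.4) for m in range(0, 1200, 60)],
            }
            grids.append(
                impute(build_grid(make_stay(obs, n_bins=240, patient_id=f"c{i}"), schema),
                       schema, "dense", small_stats)
            )
        est = PaO2Estimator(alpha_grid=(1.0,))
        est.fit(grids[:4], grids[4:])
        from respmon.oxygenation import _measurement_context

        base, y, _, ok = _measurement_context(grids[-1])
        E = np.zeros((ok.sum(), 10))
        pred = est.predict(base[ok], E)
        assert np.allclose(pred, 88.0, atol=1.0)

    def test_meta_with_zero_errors_close_to_base(self, schema, ph_shift_cohort):
        stays = ph_shift_cohort
        stats = TrainingStats.fit(stays[:40], schema)
        est = fit_pao2_estimator_on_cohort(stays[:40], stays[40:50], schema, stats)
        from respmon.oxygenation import _measurement_context

        g = impute(build_grid(stays[55], schema), schema, "dense", stats)
        base, y, _, ok = _measurement_context(g)
        if not ok.any():
            pytest.skip("no eligible bins in this stay")
        pred_meta = est.predict(base[ok], np.zeros((ok.sum(), 10)))
        pred_base = est.predict_base(base[ok])
        # ablated meta stays within the base model's error scale
        assert np.sqrt(np.mean((pred_meta - pred_base) ** 2)) < 25.0


class TestPaO2Track:
    def test_no_measurement_all_forward_fill(self, schema, small_stats):
        g = impute(build_grid(make_stay({}, n_bins=20), schema), schema, "dense", small_stats)
        est_track, src = estimate_pao2_track(g, None)
        assert np.all(src == SOURCE_FORWARD_FILL)

    def test_measured_bin_carries_measurement(self, schema, small_stats, ph_shift_cohort):
        stats = TrainingStats.fit(ph_shift_cohort[:40], schema)
        est = fit_pao2_estimator_on_cohort(
            ph_shift_cohort[:40], ph_shift_cohort[40:50], schema, stats
        )
        g = impute(build_grid(make_stay(
            {"pao2": [(0, 90.0), (100, 120.0)],
             "spo2": [(float(m), 97.0) for m in range(0, 200, 5)],
             "sao2": [(0, 97.0)], "ph": [(0, 7.4)]}, n_bins=40), schema),
            schema, "dense", stats)
        track, src = estimate_pao2_track(g, est)
        assert src[0] == SOURCE_MEASURED and src[20] == SOURCE_MEASURED
        assert track[20] == pytest.approx(120.0)
        assert np.all(src[1:20] == SOURCE_MODEL) and np.all(src[21:] == SOURCE_MODEL)


class TestFIO2:
    def test_ambient_air_default(self, schema, small_stats):
        g = impute(build_grid(make_stay({}, n_bins=20), schema), schema, "dense", small_stats)
        f = estimate_fio2_track(g, np.zeros(20, dtype=bool))
        assert np.all(f == AMBIENT_FIO2)

    def test_ventilator_fio2_when_recent_and_ventilated(self, schema, small_stats):
        g = impute(build_grid(make_stay({"fio2": [(0, 0.6)]}, n_bins=12), schema),
                   schema, "dense", small_stats)
        f = estimate_fio2_track(g, np.ones(12, dtype=bool))
        # 30-min recency: bins 0..6 within horizon (time-since <= 30)
        assert np.all(f[:7] == pytest.approx(0.6))
        assert f[8] == AMBIENT_FIO2

    def test_niv_mode_counts_as_ventilated(self, schema, small_stats):
        g = impute(build_grid(make_stay(
            {"fio2": [(0, 0.5)], "vent_mode": [(0, float(MODE_NIV))]}, n_bins=6), schema),
            schema, "dense", small_stats)
        f = estimate_fio2_track(g, np.zeros(6, dtype=bool))
        assert f[0] == pytest.approx(0.5)

    def test_supplemental_takes_precedence_over_high_flow(self, schema, small_stats):
        g = impute(build_grid(make_stay(
            {"supp_fio2": [(0, 0.35)], "hiflo_fio2": [(300, 0.5)]}, n_bins=100), schema),
            schema, "dense", small_stats)
        f = estimate_fio2_track(g, np.zeros(100, dtype=bool))
        # supplemental measured 6 h ago still beats a fresher high-flow value
        assert f[80] == pytest.approx(0.35)

    def test_high_flow_used_when_no_supplemental(self, schema, small_stats):
        g = impute(build_grid(make_stay({"hiflo_fio2": [(0, 0.5)]}, n_bins=20), schema),
                   schema, "dense", small_stats)
        f = estimate_fio2_track(g, np.zeros(20, dtype=bool))
        assert f[10] == pytest.approx(0.5)


class TestPFTrack:
    def test_constant_ratio_preserved(self):
        pf = pf_track(np.full(100, 84.0), np.full(100, 0.21), bandwidth=20)
        assert np.allclose(pf, 400.0)

    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(3)
        pao2 = rng.uniform(60, 120, 50)
        fio2 = rng.uniform(0.21, 0.8, 50)
        bw = 7.0
        out = pf_track(pao2, fio2, bandwidth=bw)
        ratio = pao2 / fio2
        half = int(np.ceil(4 * bw))
        for t in (0, 10, 25, 49):
            idx = np.arange(max(0, t - half), min(50, t + half + 1))
            w = np.exp(-0.5 * ((idx - t) / bw) ** 2)
            assert out[t] == pytest.approx(np.sum(w * ratio[idx]) / np.sum(w), rel=1e-9)

    def test_zero_bandwidth_is_raw_ratio(self):
        rng = np.random.default_rng(4)
        pao2 = rng.uniform(60, 120, 30)
        fio2 = rng.uniform(0.21, 1.0, 30)
        assert np.allclose(pf_track(pao2, fio2, bandwidth=0), pao2 / fio2)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(5)
        pao2 = rng.uniform(60, 120, 80)
        fio2 = rng.uniform(0.21, 1.0, 80)
        out = pf_track(pao2, fio2, bandwidth=5)
        shifted = pf_track(np.roll(pao2, 0), np.roll(fio2, 0), bandwidth=5)
        assert np.allclose(out, shifted)
        # interior values unaffected by identical padding on both sides
        out2 = pf_track(np.concatenate([pao2, pao2]), np.concatenate([fio2, fio2]), bandwidth=5)
        assert np.allclose(out2[25:55], pf_track(pao2, fio2, bandwidth=5)[25:55], rtol=1e-6)


class TestNoFutureLeakage:
    def test_truncating_future_preserves_estimates(self, schema, small_stats, small_cohort):
        stays, _ = small_cohort
        stay = next(s for s in stays if "pao2" in s.observations)
        p_full = process_stay(stay, schema, small_stats, with_features=False)
        n = p_full.n_steps
        t_cut = n // 2
        g_cut = p_full.grid_dense.truncate(t_cut)
        est_full, src_full = estimate_pao2_track(p_full.grid_dense, None)
        est_cut, src_cut = estimate_pao2_track(g_cut, None)
        assert np.array_equal(src_full[:t_cut], src_cut)
        assert np.allclose(est_full[:t_cut], est_cut, equal_nan=True)


class TestEstimatorSerialization:
    def test_save_load_round_trip(self, schema, small_stats, ph_shift_cohort, tmp_path):
        stays = ph_shift_cohort
        from respmon.gridding import TrainingStats

        stats = TrainingStats.fit(stays[:40], schema)
        est = fit_pao2_estimator_on_cohort(stays[:40], stays[40:50], schema, stats)
        p = tmp_path / "pao2.model"
        est.save(p)
        loaded = PaO2Estimator.load(p)
        base = np.array([[96.0, 90.0, 96.0, 7.35, 5.0, 60.0, 96.5]])
        E = np.zeros((1, 10))
        assert loaded.predict(base, E)[0] == pytest.approx(est.predict(base, E)[0])
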