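"""Relaxation-rate conversion, Boxerman fit, perfusion metrics, ROI tools."""

import numpy as np
import pandas as pd
import pytest

from gliomamap import dsc, synthetic


def _course(signal, te=0.02, tr=1.0, baseline_n=5, roi="r"):
    t = np.arange(len(signal)) * tr
    return dsc.SignalTimeCourse(roi, t, np.asarray(signal, float), te, baseline_n)


class TestDeltaR2:
    def test_flat_signal_gives_zero(self):
        c = _course([100.0] * 20)
        assert np.allclose(dsc.delta_r2(c).dr2, 0.0)

    def test_analytic_inversion(self):
        sig = np.full(20, 100.0)
        sig[10] = 100.0 * np.exp(-1.0)
        c = _course(sig, te=0.02)
        assert dsc.delta_r2(c).dr2[10] == pytest.approx(50.0)

    def test_roundtrip_with_generator(self):
        roi = pd.DataFrame({"roi_id": ["t"], "K1": [1.3], "K2": [0.04]})
        courses, _ = synthetic.generate_dsc_timecourses(
            None, snr=None, seed=2, roi_params=roi
        )
        cs = dsc.courses_from_table(courses, te=0.030, baseline_n=20)
        ref = dsc.delta_r2(cs["reference"]).dr2
        cum = dsc.cumulative_integral(cs["reference"].t, ref)
        expected = 1.3 * ref - 0.04 * cum
        assert np.allclose(dsc.delta_r2(cs["t"]).dr2, expected, atol=1e-10)

    def test_nonpositive_signal_error_names_index(self):
        sig = np.full(20, 100.0)
        sig[7] = -1.0
        with pytest.raises(ValueError, match="index 7"):
            dsc.delta_r2(_course(sig))

    def test_baseline_near_zero(self):
        roi = pd.DataFrame({"roi_id": ["t"], "K1": [1.0], "K2": [0.02]})
        courses, _ = synthetic.generate_dsc_timecourses(
            None, snr=None, seed=3, roi_params=roi
        )
        cs = dsc.courses_from_table(courses, te=0.030, baseline_n=20)
        curve = dsc.delta_r2(cs["t"])
        base = curve.dr2[: curve.baseline_n]
        assert abs(base.mean()) < 1e-9


class TestFitLeakage:
    def _ref(self):
        t = np.arange(80) * 1.5
        ref = synthetic.gamma_variate(t, 30.0, 3.0, 1.5, 25.0)
        return dsc.DeltaR2Curve("ref", t, ref, 1000.0, 20)

    def test_identity_regression(self):
        ref = self._ref()
        tum = dsc.DeltaR2Curve("t", ref.t, ref.dr2.copy(), 1000.0, 20)
        fit = dsc.fit_leakage(tum, ref)
        assert fit.k1 == pytest.approx(1.0, abs=1e-12)
        assert fit.k2 == pytest.approx(0.0, abs=1e-12)

    def test_constructed_linear_model_exact(self):
        ref = self._ref()
        cum = dsc.cumulative_integral(ref.t, ref.dr2)
        tum = dsc.DeltaR2Curve("t", ref.t, ref.dr2 - 0.3 * cum, 1000.0, 20)
        fit = dsc.fit_leakage(tum, ref)
        assert fit.k1 == pytest.approx(1.0, abs=1e-10)
        assert fit.k2 == pytest.approx(0.3, abs=1e-10)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_flat_reference_rejected(self):
        t = np.arange(60) * 1.5
        flat = dsc.DeltaR2Curve("ref", t, np.zeros(60), 1000.0, 20)
        tum = dsc.DeltaR2Curve("t", t, np.ones(60), 1000.0, 20)
        with pytest.raises(ValueError, match="collinear|no bolus"):
            dsc.fit_leakage(tum, flat, fit_window=(0, 60))

    def test_noisy_recovery_within_5_percent(self):
        roi = pd.DataFrame({"roi_id": ["tumor"], "K1": [1.2], "K2": [0.05]})
        courses, _ = synthetic.generate_dsc_timecourses(
            None, snr=50.0, seed=5, roi_params=roi
        )
        cs = dsc.courses_from_table(courses, te=0.030, baseline_n=20)
        fit = dsc.fit_leakage(
            dsc.delta_r2(cs["tumor"]), dsc.delta_r2(cs["reference"])
        )
        assert abs(fit.k1 - 1.2) / 1.2 < 0.05
        assert abs(fit.k2 - 0.05) / 0.05 < 0.05

    def test_k2_estimate_unbiased_over_seeds(self):
        roi = pd.DataFrame({"roi_id": ["tumor"], "K1": [1.2], "K2": [0.05]})
        k = []
        for seed in range(60):
            courses, _ = synthetic.generate_dsc_timecourses(
                None, snr=50.0, seed=seed, roi_params=roi.copy(),
                noise_model="gaussian",
            )
            cs = dsc.courses_from_table(courses, te=0.030, baseline_n=20)
            k.append(
                dsc.fit_leakage(
                    dsc.delta_r2(cs["tumor"]), dsc.delta_r2(cs["reference"])
                ).k2
            )
        k = np.array(k)
        assert abs(k.mean() - 0.05) < 2 * k.std(ddof=1) / np.sqrt(len(k))


class TestPerfusionMetrics:
    def _setup(self, k2_roi=0.06, k2_nawm=0.03):
        roi = pd.DataFrame(
            {"roi_id": ["tumor", "white"], "K1": [1.0, 1.0], "K2": [k2_roi, k2_nawm]}
        )
        courses, _ = synthetic.generate_dsc_timecourses(
            None, snr=None, seed=1, roi_params=roi, n_timepoints=120
        )
        cs = dsc.courses_from_table(courses, te=0.030, baseline_n=20)
        ref = dsc.delta_r2(cs["reference"])
        curves = {k: dsc.delta_r2(v) for k, v in cs.items()}
        fits = {k: dsc.fit_leakage(curves[k], ref) for k in ("tumor", "white")}
        return cs, curves, fits, ref

    def test_nk2_is_plain_ratio(self):
        cs, curves, fits, ref = self._setup()
        m = dsc.perfusion_metrics(
            cs["tumor"], curves["tumor"], fits["tumor"], ref,
            curves["white"], fits["white"],
        )
        assert m.nk2 == pytest.approx(2.0, rel=1e-6)

    def test_self_normalization(self):
        cs, curves, fits, ref = self._setup(k2_roi=0.03, k2_nawm=0.03)
        m = dsc.perfusion_metrics(
            cs["tumor"], curves["tumor"], fits["tumor"], ref,
            curves["white"], fits["white"],
        )
        assert m.rcbv == pytest.approx(1.0, rel=1e-6)
        assert m.nk2 == pytest.approx(1.0, rel=1e-6)

    def test_full_recovery_psr_near_100(self):
        roi = pd.DataFrame({"roi_id": ["t", "w"], "K1": [1.0, 1.0], "K2": [0.0, 1e-6]})
        courses, _ = synthetic.generate_dsc_timecourses(
            None, snr=None, seed=1, roi_params=roi, n_timepoints=200
        )
        cs = dsc.courses_from_table(courses, te=0.030, baseline_n=20)
        ref = dsc.delta_r2(cs["reference"])
        m = dsc.perfusion_metrics(
            cs["t"], dsc.delta_r2(cs["t"]), dsc.fit_leakage(dsc.delta_r2(cs["t"]), ref),
            ref, dsc.delta_r2(cs["w"]), dsc.fit_leakage(dsc.delta_r2(cs["w"]), ref),
        )
        assert m.psr == pytest.approx(100.0, abs=1.0)

    def test_zero_nawm_k2_gives_explicit_null(self):
        cs, curves, fits, ref = self._setup()
        fits["white"].k2 = 0.0
        m = dsc.perfusion_metrics(
            cs["tumor"], curves["tumor"], fits["tumor"], ref,
            curves["white"], fits["white"],
        )
        assert m.nk2 is None

    def test_planted_blood_volume_scaling_shows_in_rcbv(self):
        roi = pd.DataFrame({"roi_id": ["t", "w"], "K1": [1.0, 0.5], "K2": [0.0, 0.0]})
        courses, _ = synthetic.generate_dsc_timecourses(
            None, snr=200.0, seed=4, roi_params=roi
        )
        metrics = dsc.analyze_timecourses(courses, te=0.030, baseline_n=20,
                                          nawm_roi="w")
        rcbv = metrics.loc[metrics["roi_id"] == "t", "rCBV"].iloc[0]
        assert rcbv == pytest.approx(2.0, rel=0.05)

    def test_nk2_invariant_under_contrast_dose_scaling(self):
        def nk2_at_peak(peak):
            roi = pd.DataFrame(
                {"roi_id": ["t", "w"], "K1": [1.0, 1.0], "K2": [0.06, 0.03]}
            )
            courses, _ = synthetic.generate_dsc_timecourses(
                None, snr=None, seed=1, roi_params=roi,
                bolus={"t0": 30.0, "alpha": 3.0, "beta": 1.5, "peak": peak},
            )
            metrics = dsc.analyze_timecourses(
                courses, te=0.030, baseline_n=20, nawm_roi="w"
            )
            return metrics.loc[metrics["roi_id"] == "t", "nK2"].iloc[0]

        assert nk2_at_peak(25.0) == pytest.approx(nk2_at_peak(12.5), rel=1e-6)

    def test_nk2_monotone_in_roi_k2(self):
        values = []
        for k2 in (0.02, 0.04, 0.06):
            cs, curves, fits, ref = self._setup(k2_roi=k2, k2_nawm=0.03)
            m = dsc.perfusion_metrics(
                cs["tumor"], curves["tumor"], fits["tumor"], ref,
                curves["white"], fits["white"],
            )
            values.append(m.nk2)
        assert values == sorted(values)


class TestRoiTools:
    def test_constant_volume(self):
        vol = np.full((20, 20, 5), 7.5)
        mean, n_nan = dsc.extract_roi_mean(vol, (10, 10, 2))
        assert mean == 7.5 and n_nan == 0

    def test_linear_ramp_matches_loop_oracle(self):
        x, y, z = np.meshgrid(np.arange(30), np.arange(30), np.arange(6), indexing="ij")
        vol = (1.7 * x - 0.3 * y + 2.0 * z).astype(float)
        center = (15, 12, 3)
        mean, _ = dsc.extract_roi_mean(vol, center)
        acc = []
        for i in range(15 - 4, 15 + 4):
            for j in range(12 - 4, 12 + 4):
                acc.append(vol[i, j, 3])
        assert mean == pytest.approx(np.mean(acc))

    def test_even_window_anchored_low(self):
        vol = np.zeros((16, 16, 3))
        vol[4:12, 4:12, 1] = 1.0  # exactly the window for center (8, 8, 1)
        mean, _ = dsc.extract_roi_mean(vol, (8, 8, 1))
        assert mean == 1.0

    def test_all_nan_window_rejected(self):
        vol = np.full((16, 16, 3), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            dsc.extract_roi_mean(vol, (8, 8, 1))

    def test_window_outside_volume_rejected(self):
        vol = np.zeros((16, 16, 3))
        with pytest.raises(ValueError):
            dsc.extract_roi_mean(vol, (40, 40, 1))

    def test_normalize_uniform_gives_ones(self):
        vol = np.full((8, 8, 4), 3.0)
        out = dsc.normalize_map(vol, np.ones_like(vol, bool))
        assert np.allclose(out, 1.0)

    def test_normalize_scale_invariant(self, rng):
        vol = rng.uniform(1, 5, size=(8, 8, 4))
        mask = np.ones_like(vol, bool)
        assert np.allclose(dsc.normalize_map(vol, mask), dsc.normalize_map(2 * vol, mask))

    def test_normalized_median_is_one(self, rng):
        vol = rng.uniform(1, 5, size=(9, 9, 5))
        mask = vol > 2.0
        out = dsc.normalize_map(vol, mask)
        assert np.median(out[mask]) == pytest.approx(1.0)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            dsc.normalize_map(np.zeros((4, 4, 2)), np.ones((4, 4, 2), bool))
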