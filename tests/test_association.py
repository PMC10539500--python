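"""Random-intercept LMM: REML, variance shares, EMMs, screens, binning."""

import numpy as np
import pandas as pd
import pytest

from gliomamap import association as assoc


def simulate_grouped(
    n_patients=20, n_per=5, sigma_b=2.0, sigma_e=1.0, beta=(), seed=0
):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        b = rng.normal(0, sigma_b)
        for _ in range(n_per):
            x = rng.normal(size=len(beta))
            rows.append(
                {
                    "patient_id": f"P{p:02d}",
                    **{f"x{j}": x[j] for j in range(len(beta))},
                    "y": float(np.dot(beta, x)) + b + rng.normal(0, sigma_e),
                }
            )
    return pd.DataFrame(rows)


class TestReml:
    def test_one_sample_per_patient_reduces_to_ols(self):
        df = simulate_grouped(n_patients=30, n_per=1, sigma_b=0.0, beta=(1.5,), seed=1)
        fit = assoc.fit_random_intercept_lmm(df, "y", ["x0"])
        x = np.column_stack([np.ones(len(df)), df["x0"]])
        ols = np.linalg.lstsq(x, df["y"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-10)
        assert fit.sigma2_patient == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = simulate_grouped(beta=(0.7,), seed=13)
        fit = assoc.fit_random_intercept_lmm(df, "y", ["x0"])
        ref = smf.mixedlm("y ~ x0", df, groups=df["patient_id"]).fit(reml=True)
        assert fit.sigma2_patient == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-4)
        assert fit.sigma2_resid == pytest.approx(float(ref.scale), rel=1e-4)
        assert fit.beta[1] == pytest.approx(float(ref.params["x0"]), rel=1e-5)

    def test_balanced_variance_components_recovered(self):
        df = simulate_grouped(sigma_b=2.0, sigma_e=1.0, seed=13)
        fit = assoc.fit_random_intercept_lmm(df, "y", [])
        assert abs(fit.sigma2_patient - 4.0) / 4.0 < 0.5
        assert abs(fit.sigma2_resid - 1.0) < 0.3

    def test_mean_components_within_2se_over_seeds(self):
        sb, se_ = [], []
        for seed in range(200):
            df = simulate_grouped(sigma_b=2.0, sigma_e=1.0, seed=seed)
            fit = assoc.fit_random_intercept_lmm(df, "y", [])
            sb.append(fit.sigma2_patient)
            se_.append(fit.sigma2_resid)
        for est, truth in ((np.array(sb), 4.0), (np.array(se_), 1.0)):
            assert abs(est.mean() - truth) < 2 * est.std(ddof=1) / np.sqrt(len(est))

    def test_profile_optimum_beats_grid(self):
        df = simulate_grouped(seed=7)
        fit = assoc.fit_random_intercept_lmm(df, "y", [])
        grid = assoc.reml_profile(fit, np.linspace(-6, 6, 25))
        assert fit.reml_loglik >= grid.max() - 1e-8

    def test_singular_design_rejected(self):
        df = simulate_grouped(beta=(1.0,), seed=2)
        df["x1"] = df["x0"]
        with pytest.raises(ValueError, match="singular"):
            assoc.fit_random_intercept_lmm(df, "y", ["x0", "x1"])

    def test_interaction_shorthand_expands(self):
        df = simulate_grouped(seed=3)
        df["g1"] = np.where(np.arange(len(df)) % 2 == 0, "wt", "mut")
        df["g2"] = np.where(np.arange(len(df)) % 3 == 0, "neutral", "amp")
        fit = assoc.fit_random_intercept_lmm(df, "y", ["g1*g2"])
        assert list(fit.term_slices) == ["g1", "g2", "g1:g2"]
        assert fit.p == 4  # intercept + 3 dummy/interaction columns


class TestVarianceDecomposition:
    def test_saturated_binary_term_takes_everything(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "A", "B", "B"] * 5,
                "g": ["wt", "mut"] * 10,
            }
        )
        df["y"] = np.where(df["g"] == "mut", 2.0, 0.0)
        fit = assoc.fit_random_intercept_lmm(df, "y", ["g"])
        vd = assoc.variance_decomposition(fit)
        share = vd.loc[vd["term"] == "g", "percent_variance"].iloc[0]
        assert share == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_terms_split_4_to_1(self):
        # balanced orthogonal +/-1 design, effects 2 and 1, no noise
        rows = []
        for p in range(10):
            for a in (-1.0, 1.0):
                for b in (-1.0, 1.0):
                    rows.append({"patient_id": f"P{p}", "a": a, "b": b,
                                 "y": 2.0 * a + 1.0 * b})
        df = pd.DataFrame(rows)
        fit = assoc.fit_random_intercept_lmm(df, "y", ["a", "b"])
        vd = assoc.variance_decomposition(fit).set_index("term")
        sa = vd.loc["a", "percent_variance"]
        sb = vd.loc["b", "percent_variance"]
        assert sa / (sa + sb) == pytest.approx(0.8, abs=1e-9)

    def test_null_shares_average_df_over_n(self):
        shares = []
        for seed in range(100):
            df = simulate_grouped(n_patients=10, n_per=4, sigma_b=0.0,
                                  sigma_e=1.0, beta=(0.0,), seed=seed)
            fit = assoc.fit_random_intercept_lmm(df, "y", ["x0"])
            vd = assoc.variance_decomposition(fit).set_index("term")
            shares.append(vd.loc["x0", "percent_variance"])
        # one spent df over n=40 observations -> ~2.5% mean share
        assert np.mean(shares) == pytest.approx(100 * 1 / 40, abs=1.0)


class TestEmm:
    def test_balanced_design_equals_group_means(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "patient_id": np.repeat([f"P{i}" for i in range(10)], 4),
                "g": ["a", "a", "b", "b"] * 10,
                "y": rng.normal(size=40),
            }
        )
        fit = assoc.fit_random_intercept_lmm(df, "y", ["g"])
        emm = assoc.estimated_marginal_means(fit, "g")["emmeans"].set_index("level")
        raw = df.groupby("g")["y"].mean()
        assert emm.loc["a", "emmean"] == pytest.approx(raw["a"], abs=1e-6)
        assert emm.loc["b", "emmean"] == pytest.approx(raw["b"], abs=1e-6)

    def test_identical_groups_not_flagged(self):
        # both factor levels observe exactly the same values in every patient
        rng = np.random.default_rng(6)
        rows = []
        for i in range(30):
            y = rng.normal()
            for g in ("a", "b"):
                rows.append({"patient_id": f"P{i % 10}", "g": g, "y": y})
        fit = assoc.fit_random_intercept_lmm(pd.DataFrame(rows), "y", ["g"])
        out = assoc.estimated_marginal_means(fit, "g")
        contrast = out["contrasts"].iloc[0]
        assert abs(contrast["estimate"]) < 1e-6
        assert contrast["p_tukey"] > 0.95

    def test_ci_contains_mean(self):
        df = simulate_grouped(seed=8)
        df["g"] = np.where(np.arange(len(df)) % 3 == 0, "a", "b")
        fit = assoc.fit_random_intercept_lmm(df, "y", ["g"])
        emm = assoc.estimated_marginal_means(fit, "g")["emmeans"]
        assert ((emm["ci_low"] <= emm["emmean"]) & (emm["emmean"] <= emm["ci_high"])).all()

    def test_tukey_power_on_planted_three_groups(self):
        flagged_correct = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for g, mu in zip("abc", (0.0, 0.0, 1.0)):
                for i in range(30):
                    rows.append(
                        {"patient_id": f"P{i % 10}", "g": g,
                         "y": mu + rng.normal(0, 0.5)}
                    )
            df = pd.DataFrame(rows)
            fit = assoc.fit_random_intercept_lmm(df, "y", ["g"])
            con = assoc.estimated_marginal_means(fit, "g")["contrasts"]
            sig = set(con.loc[con["p_tukey"] < 0.05, "contrast"])
            if sig == {"a - c", "b - c"}:
                flagged_correct += 1
        assert flagged_correct / n_seeds >= 0.90

    def test_unknown_factor_rejected(self):
        df = simulate_grouped(seed=1, beta=(1.0,))
        fit = assoc.fit_random_intercept_lmm(df, "y", ["x0"])
        with pytest.raises(ValueError):
            assoc.estimated_marginal_means(fit, "x0")  # continuous, not a factor


class TestScreenAndBinning:
    def test_identity_signature_gives_unit_slope(self):
        df = simulate_grouped(seed=4, beta=(1.0,))
        df["region"] = "CE"
        df["sig"] = df["y"]
        out = assoc.signature_screen(df, ["y"], ["sig"])
        row = out.iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["lmm_slope"] == pytest.approx(1.0, abs=1e-6)

    def test_patient_confounded_null_controlled_by_lmm(self):
        # y and the signature have independent patient-level offsets that
        # happen to align across these 8 patients: the raw correlation is
        # strongly significant while the within-patient LMM slope is null
        rng = np.random.default_rng(2)
        rows = []
        for p in range(8):
            b, c = rng.normal(0, 2), rng.normal(0, 2)
            for _ in range(8):
                rows.append(
                    {"patient_id": f"P{p}", "region": "NE",
                     "sig": c + rng.normal(0, 0.3), "y": b + rng.normal(0, 0.3)}
                )
        out = assoc.signature_screen(pd.DataFrame(rows), ["y"], ["sig"], stratum="NE")
        row = out.iloc[0]
        assert row["pearson_p"] < 1e-3
        assert abs(row["lmm_slope"]) < abs(row["pearson_r"]) / 3
        assert row["lmm_slope_p"] > 0.05

    def test_small_stratum_skipped_with_warning(self, caplog):
        df = simulate_grouped(seed=2, beta=(1.0,)).head(2)
        df["region"] = "NE"
        df["sig"] = 1.0
        with caplog.at_level("WARNING"):
            out = assoc.signature_screen(df, ["y"], ["sig"], stratum="NE")
        assert out.empty

    def test_median_bin_splits_1_to_10(self):
        bins = assoc.median_bin(range(1, 11))
        assert (bins == "high").sum() == 5
        assert (bins == "low").sum() == 5

    def test_median_tie_goes_low(self):
        bins = assoc.median_bin([1.0, 2.0, 3.0])
        assert bins.iloc[1] == "low"

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            assoc.median_bin([2.0, 2.0, 2.0])

    def test_matches_sort_oracle(self, rng):
        v = rng.normal(size=31)
        bins = assoc.median_bin(v)
        med = np.median(v)
        assert ((v > med) == (bins == "high").to_numpy()).all()
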