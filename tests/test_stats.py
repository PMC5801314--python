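"""Hierarchical regression machinery, VIF, residual normality, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sst

from mmndecay import cognition
from mmndecay.simulate import MEMORY_VARS, SimulationConfig, cohort_frame, simulate_cohort
from mmndecay.stats import (
    HierarchicalRegression,
    fit_deviant_interaction,
    fit_hierarchical,
    pearson_r,
    residual_normality,
    vif_diagnostics,
)


def toy_data(n=80, seed=0, coef=0.0):
    rng = np.random.default_rng(seed)
    age = rng.normal(70, 6, n)
    edu = rng.normal(11, 2, n)
    x = rng.standard_normal(n)
    y = -0.05 * age + 0.04 * edu + coef * x + rng.standard_normal(n)
    return pd.DataFrame(
        {"memory": y, "age_years": age, "education_years": edu, "x": x}
    )


class TestHierarchical:
    def test_outcome_equal_to_added_predictor(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "age_years": rng.normal(70, 6, 50),
                "education_years": rng.normal(11, 2, 50),
                "x": rng.standard_normal(50),
            }
        )
        df["memory"] = df["x"]
        res = fit_hierarchical(df, "memory", added="x")
        assert res.r2_full == pytest.approx(1.0, abs=1e-10)
        assert res.std_beta_full["x"] == pytest.approx(1.0, abs=1e-8)

    def test_null_added_predictor_contributes_nothing(self):
        res = fit_hierarchical(toy_data(n=4000, seed=2, coef=0.0), "memory", added="x")
        assert res.delta_r2 < 0.002

    def test_nested_f_matches_anova_route(self):
        """ΔR²-based F equals the sums-of-squares F from anova_lm."""
        from statsmodels.stats.anova import anova_lm

        df = toy_data(n=60, seed=3, coef=0.3)
        res = fit_hierarchical(df, "memory", added="x")
        tbl = anova_lm(res.reduced, res.full)
        assert res.f_change == pytest.approx(float(tbl["F"].iloc[1]), rel=1e-10)
        assert res.p_change == pytest.approx(float(tbl["Pr(>F)"].iloc[1]), rel=1e-8)

    def test_standardized_beta_matches_closed_form(self):
        """β of the added predictor equals B * sd(x) / sd(y)."""
        df = toy_data(n=60, seed=4, coef=0.3)
        res = fit_hierarchical(df, "memory", added="x")
        expected = res.full.params["x"] * df["x"].std(ddof=1) / df["memory"].std(ddof=1)
        assert res.std_beta_full["x"] == pytest.approx(expected, rel=1e-10)

    def test_delta_r2_nonnegative(self):
        res = fit_hierarchical(toy_data(n=40, seed=5), "memory", added="x")
        assert res.delta_r2 >= 0.0
        m, df2 = res.df_change
        assert m == 1 and df2 == 40 - 3 - 1 + 0  # n - k_full - 1

    def test_rank_deficient_design_named(self):
        df = toy_data(n=40, seed=6)
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="collinear"):
            fit_hierarchical(df, "memory", added=("x", "x2"))

    def test_summary_layout(self):
        res = fit_hierarchical(toy_data(n=50, seed=7, coef=0.4), "memory", added="x")
        text = res.summary()
        assert "Model 1" in text and "Model 2" in text
        assert "F_change" in text and "Shapiro-Wilk" in text


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        out = vif_diagnostics(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)
        np.testing.assert_allclose(out["tolerance"], 1.0, atol=1e-10)
        assert not out["flag"].any()

    def test_correlated_pair_closed_form(self):
        """r = 0.9 exactly -> VIF = 1 / (1 - 0.81) ≈ 5.263."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal(500)
        e = rng.standard_normal(500)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # residualize exactly
        y = 0.9 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.81) * (e - e.mean()) / e.std()
        r = np.corrcoef(x, y)[0, 1]
        out = vif_diagnostics(pd.DataFrame({"x": x, "y": y}))
        np.testing.assert_allclose(out["vif"], 1.0 / (1.0 - r**2), rtol=1e-8)

    def test_duplicate_predictor_flagged_or_error(self):
        x = np.random.default_rng(9).standard_normal(30)
        out = vif_diagnostics(pd.DataFrame({"x": x, "x2": x + 1e-9 * np.arange(30)}))
        assert out["flag"].all()

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif_diagnostics(pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)}))


class TestResidualNormality:
    def test_gaussian_residual_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = rng.standard_normal(60)
            X = sm.add_constant(rng.standard_normal(60))
            _, p = residual_normality(sm.OLS(y, X).fit())
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.035)

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(50):
            y = rng.standard_t(1.5, 200)
            X = sm.add_constant(rng.standard_normal(200))
            _, p = residual_normality(sm.OLS(y, X).fit())
            rejections += p < 0.05
        assert rejections / 50 > 0.5

    def test_tiny_sample_rejected(self):
        fit = sm.OLS([1.0, 2.0], sm.add_constant([0.0, 1.0])).fit()
        with pytest.raises(ValueError):
            residual_normality(fit)


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_independent_large_n_small(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        assert abs(pearson_r(x, y)) < 3 / np.sqrt(2000)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestDeviantInteraction:
    @staticmethod
    def wide_scores(n=120, seed=13, effect=0.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "age_years": rng.normal(70, 6, n),
                "education_years": rng.normal(11, 2, n),
            }
        )
        fams = ("duration", "gap", "frequency", "intensity", "location")
        for fam in fams:
            df[f"opt1_{fam}"] = rng.normal(-1.5, 1.0, n)
        df["memory"] = (
            -0.05 * df["age_years"]
            + effect * df["opt1_duration"]
            + rng.standard_normal(n)
        )
        return df, fams

    def test_null_block_not_significant_on_average(self):
        ps = []
        for seed in range(25):
            df, fams = self.wide_scores(seed=100 + seed)
            res = fit_deviant_interaction(df, "memory", fams)
            ps.append(res.p_change)
        assert np.mean(np.array(ps) < 0.05) < 0.25  # near the nominal rate

    def test_single_family_degenerates_to_hierarchical(self):
        df, _ = self.wide_scores(seed=14)
        a = fit_deviant_interaction(df, "memory", ("duration",))
        b = fit_hierarchical(df, "memory", added="opt1_duration")
        assert a.f_change == pytest.approx(b.f_change)
        assert a.delta_r2 == pytest.approx(b.delta_r2)

    def test_identical_family_scores_rejected(self):
        df, fams = self.wide_scores(seed=15)
        for fam in fams:
            df[f"opt1_{fam}"] = df["opt1_duration"]
        with pytest.raises(ValueError, match="collinear"):
            fit_deviant_interaction(df, "memory", fams)

    def test_missing_family_rejected(self):
        df, fams = self.wide_scores(seed=16)
        with pytest.raises(ValueError, match="gap2"):
            fit_deviant_interaction(df, "memory", ("duration", "gap2"))


def test_true_coupling_recovered_without_measurement_noise():
    """Regressing the memory composite on the *latent* decay score recovers
    the generative standardized coupling (up to composite reliability) at
    n = 200, within ±0.1 on the Monte-Carlo mean."""
    betas = []
    for seed in range(40):
        cfg = SimulationConfig(
            n_per_group={"SMI": 66, "naMCI": 67, "aMCI": 67}, seed=seed
        )
        df = cohort_frame(simulate_cohort(cfg, seed=seed)).set_index("subject_id")
        bat = df[[*MEMORY_VARS, "tmt_a", "tmt_b", "digit_span", "digit_symbol",
                  "word_fluency", "ecb_computation_span"]]
        z, means, sds = cognition.zstandardize(cognition.orient_battery(bat))
        weights = cognition.extract_components(z)
        comps = cognition.build_composites(z, weights)
        mem_comp = [c for c in weights.included if "mvgt_encoding" in weights.included[c]][0]
        data = pd.DataFrame(
            {
                "memory": comps[mem_comp],
                "age_years": df["age_years"],
                "education_years": df["education_years"],
                "delta": df["true_delta_uv"],
            }
        )
        res = fit_hierarchical(data, "memory", added="delta")
        betas.append(res.std_beta_full["delta"])
    assert np.mean(betas) == pytest.approx(0.4, abs=0.1)
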