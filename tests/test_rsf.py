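"""Used-available design, Laplace GLMM, term deletion, and reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

import statsmodels.api as sm

from habsel.glmm import (
    CLASS_LEVELS,
    RandomSpec,
    build_fixed_matrix,
    fit_glmm,
    irls_logistic,
    reduce_re_structure,
)
from habsel.grid import CovariateStack, GridSpec
from habsel.rsf import (
    build_design,
    fixed_effects_table,
    lrt_term_deletion,
    odds_ratios,
    predict_rsf_map,
    r2_nakagawa,
    sample_in_polygons,
)


def expit(x):
    return 1 / (1 + np.exp(-x))


def simulate_design(
    n_groups=12,
    n_per_group=150,
    beta=None,
    sigma_intercept=0.5,
    sigma_slope=0.0,
    class_effects=None,
    interaction=None,
    seed=0,
):
    """Logistic mixed design with known truth.

    ``beta`` maps covariate name -> slope; ``interaction`` maps
    (covariate, class) -> extra slope for that class.
    """
    rng = np.random.default_rng(seed)
    beta = beta if beta is not None else {"x1": 0.8, "x2": -0.5}
    rows = []
    for g in range(n_groups):
        cls = CLASS_LEVELS[g % 4]
        u0 = rng.normal(0, sigma_intercept)
        us = {k: rng.normal(0, sigma_slope) for k in beta} if sigma_slope else {}
        X = {k: rng.normal(size=n_per_group) for k in beta}
        eta = np.full(n_per_group, -1.0 + u0)
        for k, b in beta.items():
            eta += (b + us.get(k, 0.0)) * X[k]
        if class_effects:
            eta += class_effects.get(cls, 0.0)
        if interaction:
            for (cov, icls), b in interaction.items():
                if icls == cls:
                    eta += b * X[cov]
        y = (rng.uniform(size=n_per_group) < expit(eta)).astype(int)
        df = pd.DataFrame(X)
        df["used"] = y
        df["class"] = cls
        df["individual"] = f"I{g // 2}"
        df["range_id"] = f"R{g}"
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestLaplaceOracle:
    def test_zero_variance_equals_irls_logistic(self):
        """With no random effects the Laplace fit must reproduce ordinary
        logistic regression (statsmodels GLM as the independent oracle)."""
        design = simulate_design(seed=1)
        fit = fit_glmm(design, ["x1", "x2", "class"], random=None)
        X, names = build_fixed_matrix(design, ["x1", "x2", "class"])
        oracle = sm.GLM(design["used"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta.to_numpy(), oracle.params, atol=1e-6)
        assert np.allclose(fit.se.to_numpy(), oracle.bse, rtol=1e-3)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_own_irls_matches_statsmodels(self):
        design = simulate_design(seed=2)
        X, _ = build_fixed_matrix(design, ["x1", "x2"])
        beta = irls_logistic(design["used"].to_numpy(float), X)
        oracle = sm.GLM(design["used"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(beta, oracle.params, atol=1e-8)

    def test_response_flip_negates_beta(self):
        design = simulate_design(seed=3)
        spec = RandomSpec(group="range_id")
        fit = fit_glmm(design, ["x1", "x2"], spec)
        flipped = design.assign(used=1 - design["used"])
        fit2 = fit_glmm(flipped, ["x1", "x2"], spec)
        assert np.allclose(fit.beta.to_numpy(), -fit2.beta.to_numpy(), atol=2e-3)


class TestRecovery:
    def test_beta_recovery_with_random_intercept(self):
        """Known fixed effects recovered within 3 SEs; estimates track the
        truth across seeds."""
        truth = {"x1": 0.8, "x2": -0.5, "x3": 0.3}
        betas, ses = [], []
        for seed in range(4):
            design = simulate_design(n_groups=16, n_per_group=150, beta=truth,
                                     sigma_intercept=0.5, seed=10 + seed)
            fit = fit_glmm(design, ["x1", "x2", "x3"],
                           RandomSpec(group="range_id"))
            betas.append([fit.beta[k] for k in truth])
            ses.append([fit.se[k] for k in truth])
            for k in truth:
                assert abs(fit.beta[k] - truth[k]) < 3 * fit.se[k]
        mean_b = np.mean(betas, axis=0)
        assert np.corrcoef(mean_b, list(truth.values()))[0, 1] > 0.95

    def test_intercept_variance_estimated(self):
        design = simulate_design(n_groups=24, n_per_group=200,
                                 sigma_intercept=1.0, seed=42)
        fit = fit_glmm(design, ["x1", "x2"], RandomSpec(group="range_id"))
        assert 0.3 < fit.re_variances["(intercept)"] < 2.5


class TestReduceRE:
    def test_zero_slope_variance_removed(self):
        removed = 0
        for seed in range(4):
            design = simulate_design(n_groups=12, n_per_group=120,
                                     sigma_intercept=0.6, sigma_slope=0.0,
                                     seed=20 + seed)
            spec, fit = reduce_re_structure(
                design, ["x1", "x2"],
                RandomSpec(group="range_id", slopes=("x1",)))
            removed += "x1" not in spec.slopes
        assert removed >= 3

    def test_large_intercept_variance_retained(self):
        design = simulate_design(n_groups=20, n_per_group=150,
                                 sigma_intercept=1.2, seed=30)
        spec, fit = reduce_re_structure(design, ["x1", "x2"],
                                        RandomSpec(group="range_id"))
        assert spec.intercept
        assert fit.re_variances["(intercept)"] > 0.1


class TestLRT:
    def test_type_one_error_calibrated(self):
        """Null covariate: LRT rejection rate near the nominal 0.05."""
        rejections = 0
        n_sim = 60
        for seed in range(n_sim):
            design = simulate_design(n_groups=8, n_per_group=80,
                                     beta={"x1": 0.8, "xnull": 0.0},
                                     sigma_intercept=0.0, seed=100 + seed)
            table, kept, _ = lrt_term_deletion(
                design, ["x1", "xnull", "class"], random=None)
            row = table[table["term"] == "xnull"].iloc[0]
            rejections += row["p"] < 0.05
        assert 0.01 <= rejections / n_sim <= 0.12

    def test_opposite_sign_interaction_retained(self):
        """A class-reversed slope (one class selects against the covariate
        the others select for) keeps the interaction term."""
        kept_count = 0
        for seed in range(5):
            design = simulate_design(
                n_groups=16, n_per_group=150,
                beta={"precip": 0.6, "x2": -0.5},
                interaction={("precip", "subadult male"): -1.3},
                sigma_intercept=0.3, seed=200 + seed)
            table, kept, final = lrt_term_deletion(
                design, ["precip", "x2", "class", ("precip", "class")],
                RandomSpec(group="range_id"))
            kept_count += ("precip", "class") in kept
        assert kept_count >= 4

    def test_interaction_df_is_three(self):
        design = simulate_design(n_groups=8, n_per_group=60,
                                 beta={"x1": 0.5}, seed=7)
        table, _, _ = lrt_term_deletion(
            design, ["x1", "class", ("x1", "class")], random=None)
        row = table[table["term"] == "x1:class"].iloc[0]
        assert row["df"] == 3


class TestOddsRatios:
    def test_reported_worked_examples(self):
        # printed-table worked examples: beta 0.42 (SE 0.09) and 0.05 (0.10)
        out = odds_ratios([0.42, 0.05, 0.0], [0.09, 0.10, 0.2])
        assert out["or_2dp"].tolist()[0] == 1.52
        # printed CI bound 1.27 came from unrounded inputs; printed-precision
        # inputs land within one rounding step of it
        assert out["ci_low"].tolist()[0] == pytest.approx(1.27, abs=0.015)
        assert out["or_2dp"].tolist()[1] == 1.05
        assert out["ci_low_2dp"].tolist()[1] == 0.86
        assert out["or_2dp"].tolist()[2] == 1.00

    def test_ci_brackets_or(self):
        out = odds_ratios([0.3, -1.2], [0.1, 0.4])
        assert (out["ci_low"] < out["or"]).all()
        assert (out["or"] < out["ci_high"]).all()


class TestR2:
    def test_zero_beta_zero_marginal(self):
        design = simulate_design(seed=4)
        fit = fit_glmm(design, ["x1"], random=None)
        fit.beta[:] = 0.0
        m, c = r2_nakagawa(fit, design)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_conditional_at_least_marginal(self):
        design = simulate_design(n_groups=8, n_per_group=80,
                                 sigma_intercept=0.8, seed=5)
        fit = fit_glmm(design, ["x1", "x2"], RandomSpec(group="range_id"))
        m, c = r2_nakagawa(fit, design)
        assert 0 <= m <= c <= 1

    def test_zero_random_variance_equal(self):
        design = simulate_design(seed=6)
        fit = fit_glmm(design, ["x1", "x2"], random=None)
        m, c = r2_nakagawa(fit, design)
        assert m == pytest.approx(c)


@pytest.fixture(scope="module")
def design_inputs():
    g = GridSpec(ncols=40, nrows=40, cellsize=250.0)
    rng = np.random.default_rng(11)
    stack = CovariateStack(grid=g, layers={
        "a": rng.normal(size=(40, 40)), "b": rng.normal(size=(40, 40))})
    poly = box(1_000, 1_000, 6_000, 4_000)
    used = {"R1": pd.DataFrame({
        "x": rng.uniform(1_500, 5_500, 100),
        "y": rng.uniform(1_500, 3_500, 100)})}
    info = {"R1": {"polygons": [poly], "individual": "I1",
                   "class": "adult female"}}
    return used, info, stack


class TestBuildDesign:
    def test_ratio_and_containment(self, design_inputs):
        used, info, stack = design_inputs
        design, record = build_design(used, info, stack, ["a", "b"], seed=0)
        assert (design["used"] == 0).sum() == 4 * (design["used"] == 1).sum()
        avail = design[design["used"] == 0]
        poly = info["R1"]["polygons"][0]
        import shapely
        assert shapely.contains_xy(poly, avail["x"].to_numpy(),
                                   avail["y"].to_numpy()).all()
        # shared standardization record covers both covariates
        assert set(record) == {"a", "b"}
        assert abs(design["a"].mean()) < 1e-9

    def test_available_points_uniform(self):
        """Chi-square test of counts over equal-area quadrants."""
        poly = box(0, 0, 8_000, 8_000)
        rng = np.random.default_rng(3)
        pts = sample_in_polygons([poly], 10_000, rng)
        qx = (pts[:, 0] > 4_000).astype(int)
        qy = (pts[:, 1] > 4_000).astype(int)
        counts = np.bincount(qx * 2 + qy, minlength=4)
        chi2 = ((counts - 2_500.0) ** 2 / 2_500.0).sum()
        assert stats.chi2.sf(chi2, 3) > 0.01

    def test_used_outside_raster_raises(self, design_inputs):
        used, info, stack = design_inputs
        bad = {"R1": pd.DataFrame({"x": [1e6], "y": [1e6]})}
        with pytest.raises(ValueError, match="outside"):
            build_design(bad, info, stack, ["a"], seed=0)


class TestPredictMap:
    def make_fit(self, design, terms, random=None):
        return fit_glmm(design, terms, random)

    def test_sign_flipped_class_map_direction(self):
        g = GridSpec(ncols=10, nrows=10, cellsize=1.0)
        grad = np.tile(np.linspace(-2, 2, 10), (10, 1))
        stack = CovariateStack(grid=g, layers={"precip": grad})
        beta = pd.Series({"(Intercept)": 0.0, "precip": 0.6,
                          "precip:subadult male": -1.3})
        from habsel.glmm import GLMMFit
        fit = GLMMFit(beta=beta, se=beta * 0 + 0.1, vcov=np.eye(3),
                      re_variances={}, re_correlation=None, loglik=0.0,
                      aic=0.0, converged=True, singular=False,
                      fixed_terms=["precip", ("precip", "class")])
        ref = predict_rsf_map(fit, stack, "adult female", rescale=False)
        sub = predict_rsf_map(fit, stack, "subadult male", rescale=False)
        assert np.all(np.diff(ref, axis=1) > 0)      # increasing in precip
        assert np.all(np.diff(sub, axis=1) < 0)      # reversed for the class
        scaled = predict_rsf_map(fit, stack, "adult female", rescale=True)
        assert scaled.min() == 0.0 and scaled.max() == 1.0

    def test_constant_layers_constant_map(self):
        g = GridSpec(ncols=5, nrows=5, cellsize=1.0)
        stack = CovariateStack(grid=g, layers={"precip": np.zeros((5, 5))})
        from habsel.glmm import GLMMFit
        beta = pd.Series({"(Intercept)": 0.3, "precip": 0.6})
        fit = GLMMFit(beta=beta, se=beta * 0 + 0.1, vcov=np.eye(2),
                      re_variances={}, re_correlation=None, loglik=0.0,
                      aic=0.0, converged=True, singular=False,
                      fixed_terms=["precip"])
        w = predict_rsf_map(fit, stack, "adult female", rescale=False)
        assert np.ptp(w) == 0.0


class TestReportTable:
    def test_table_layout(self):
        design = simulate_design(n_groups=8, n_per_group=80, seed=9)
        fit = fit_glmm(design, ["x1", "x2", "class"], random=None)
        tab = fixed_effects_table(fit, r2=(0.2, 0.4))
        assert list(tab.columns) == ["beta", "se", "z", "p_z", "or_95ci"]
        assert len(tab) == len(fit.beta)
        assert tab.attrs["r2_conditional"] >= tab.attrs["r2_marginal"]
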