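import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from aircount.detection import (
    AdditiveLogisticDetector,
    LogisticDetector,
    PerfectSeparationError,
    StepwiseSelector,
    build_response,
    load_fit,
    mcfadden_r2,
    predict_with_ci,
    save_fit,
)
from aircount.simulate import SimulationConfig, simulate_bernoulli_design


def direct_mle(y, X):
    """Independent oracle: numerically maximize the written-out Bernoulli log-likelihood."""
    D = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)

    def nll(b):
        eta = D @ b
        return -(y * eta - np.logaddexp(0.0, eta)).sum()

    res = minimize(nll, np.zeros(D.shape[1]), method="BFGS", options=dict(gtol=1e-12))
    return res.x, -res.fun


class TestBuildResponse:
    @pytest.mark.parametrize(
        "role, klasses, expected_y",
        [
            ("detection", ["unique_detection", "missed"], [1, 0]),
            ("false", ["unique_detection", "duplicate", "false_positive"], [0, 0, 1]),
            ("duplicate", ["unique_detection", "duplicate"], [0, 1]),
        ],
    )
    def test_role_responses(self, four_row_table, role, klasses, expected_y):
        sub = pd.concat(
            [four_row_table[four_row_table["klass"] == k] for k in klasses]
        ).reset_index(drop=True)
        y, X = build_response(sub, role)
        assert y.tolist() == expected_y
        assert len(X) == len(y)

    def test_role_row_filters(self, campaign):
        table, _ = campaign
        comp = table["klass"].value_counts()
        y_det, _ = build_response(table, "detection")
        assert len(y_det) == comp["unique_detection"] + comp["missed"]
        y_false, _ = build_response(table, "false")
        assert len(y_false) == len(table) - comp["missed"]
        y_dup, _ = build_response(table, "duplicate")
        assert len(y_dup) == comp["unique_detection"] + comp["duplicate"]

    def test_absent_covariate_rejected(self, four_row_table):
        broken = four_row_table.drop(columns=["dist_nearest"])
        broken["dist_nearest"] = np.nan
        with pytest.raises(ValueError, match="dist_nearest"):
            build_response(broken, "duplicate")

    def test_unknown_role_rejected(self, four_row_table):
        with pytest.raises(ValueError, match="unknown role"):
            build_response(four_row_table, "spurious")


class TestLogisticDetector:
    def test_intercept_only_symmetry(self):
        fit = LogisticDetector(covariates=[]).fit(pd.DataFrame(index=range(4)), [1, 0, 1, 0])
        assert abs(fit.coef_["intercept"]) < 1e-10
        assert fit.aic_ == pytest.approx(-2 * fit.loglik_ + 2)

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 25:
            n = int(rng.integers(12, 31))
            k = int(rng.integers(1, 3))
            X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{j}" for j in range(k)])
            beta = rng.normal(scale=0.8, size=k + 1)
            y = (rng.uniform(size=n) < expit(beta[0] + X.to_numpy() @ beta[1:])).astype(int)
            if y.min() == y.max():
                continue
            try:
                fit = LogisticDetector().fit(X, y)
            except (PerfectSeparationError, ValueError):
                continue
            b_star, ll_star = direct_mle(y, X)
            assert np.abs(fit.coef_.to_numpy() - b_star).max() < 1e-4
            assert fit.loglik_ >= ll_star - 1e-6
            checked += 1

    def test_single_class_response_rejected(self):
        with pytest.raises(ValueError, match="success and one failure"):
            LogisticDetector(covariates=[]).fit(pd.DataFrame(index=range(3)), [1, 1, 1])

    def test_perfect_separation_names_covariate(self):
        X = pd.DataFrame({"temperature": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        with pytest.raises(PerfectSeparationError, match="temperature"):
            LogisticDetector().fit(X, [0, 0, 0, 1, 1, 1])

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="rank-deficient"):
            LogisticDetector().fit(X, [0, 1, 0, 1])

    def test_nested_useless_parameter_costs_about_two_aic(self):
        y, X = simulate_bernoulli_design("detection", 20_000, (0.5, -0.05, -0.01), SimulationConfig(seed=2))
        small = LogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
        big = LogisticDetector(covariates=["temperature", "dist_edge", "wind_speed"]).fit(X, y)
        assert 0 < big.aic_ - small.aic_ <= 2.1

    def test_wald_slope_coverage_over_replicates(self):
        # nominal 95% intervals should cover the generating slopes in >= 90% of fits
        beta = (6.5, -0.1879, -0.0233)
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        covered = np.zeros(2)
        n_rep = 200
        for _ in range(n_rep):
            y, X = simulate_bernoulli_design("detection", 250, beta, cfg, rng=rng)
            if y.min() == y.max():
                continue
            fit = LogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
            for j, name in enumerate(["temperature", "dist_edge"]):
                lo = fit.coef_[name] - 1.96 * fit.se_[name]
                hi = fit.coef_[name] + 1.96 * fit.se_[name]
                covered[j] += lo <= beta[j + 1] <= hi
        assert np.all(covered / n_rep >= 0.90)


class TestPredictionIntervals:
    def test_closed_form_logit_interval(self):
        fit = LogisticDetector(covariates=[])
        fit.covariates_ = []
        fit.names_ = ["intercept"]
        fit.coef_ = pd.Series([0.0], index=fit.names_)
        fit.cov_ = np.array([[1.0]])
        out = predict_with_ci(fit, pd.DataFrame(index=[0]), z=1.96)
        # closed form: invlogit(0 -/+ 1.96 * 1) = 1 / (1 + exp(+/-1.96))
        assert out.loc[0, "fit"] == pytest.approx(0.5)
        assert out.loc[0, "lower"] == pytest.approx(1 / (1 + np.exp(1.96)), abs=1e-12)
        assert out.loc[0, "upper"] == pytest.approx(1 / (1 + np.exp(-1.96)), abs=1e-12)
        assert out.loc[0, "lower"] == pytest.approx(0.123, abs=1e-3)
        assert out.loc[0, "upper"] == pytest.approx(0.877, abs=1e-3)

    def test_zero_se_collapses_interval(self):
        fit = LogisticDetector(covariates=[])
        fit.covariates_ = []
        fit.names_ = ["intercept"]
        fit.coef_ = pd.Series([0.3], index=fit.names_)
        fit.cov_ = np.array([[0.0]])
        out = fit.predict_interval(pd.DataFrame(index=[0]))
        assert out.loc[0, "lower"] == out.loc[0, "fit"] == out.loc[0, "upper"]

    def test_limits_ordered_and_within_unit_interval(self, campaign):
        table, _ = campaign
        y, X = build_response(table, "detection")
        fit = LogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
        out = fit.predict_interval(X)
        assert ((0 <= out["lower"]) & (out["lower"] <= out["fit"])
                & (out["fit"] <= out["upper"]) & (out["upper"] <= 1)).all()


class TestMcFadden:
    def test_null_model_scores_zero(self):
        fit = LogisticDetector(covariates=[]).fit(pd.DataFrame(index=range(6)), [1, 0, 1, 0, 1, 0])
        assert mcfadden_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_informative_fit_scores_positive_below_one(self):
        y, X = simulate_bernoulli_design("detection", 2000, (6.5, -0.1879, -0.0233), SimulationConfig(seed=5))
        fit = LogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
        assert 0.0 < mcfadden_r2(fit) < 1.0


class TestAdditiveDetector:
    def test_linear_truth_keeps_additive_aic_within_two(self):
        y, X = simulate_bernoulli_design("detection", 400, (1.0, -0.08, -0.01), SimulationConfig(seed=3))
        lin = LogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
        gam = AdditiveLogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
        assert abs(gam.aic_ - lin.aic_) <= 2.0

    def test_infinite_penalty_recovers_linear_deviance(self):
        y, X = simulate_bernoulli_design("detection", 300, (1.0, -0.08, -0.01), SimulationConfig(seed=4))
        lin = LogisticDetector(covariates=["temperature", "dist_edge"]).fit(X, y)
        gam = AdditiveLogisticDetector(covariates=["temperature", "dist_edge"], alpha=1e12).fit(X, y)
        assert gam.deviance_ == pytest.approx(lin.deviance_, abs=0.01)

    def test_detects_genuine_nonlinearity(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-2, 2, 600)
        y = (rng.uniform(size=600) < expit(1.5 * np.sin(2.2 * x))).astype(int)
        X = pd.DataFrame({"x": x})
        lin = LogisticDetector().fit(X, y)
        gam = AdditiveLogisticDetector().fit(X, y)
        assert lin.aic_ - gam.aic_ > 2.0

    def test_small_basis_rejected(self):
        with pytest.raises(ValueError, match="basis_size"):
            AdditiveLogisticDetector(basis_size=2).fit(pd.DataFrame({"x": [0.1, 0.5, 0.9, 0.2]}), [0, 1, 0, 1])


class TestStepwiseSelector:
    def test_pure_noise_usually_selects_null(self):
        # under the null each covariate advances with prob ~ alpha, so the
        # null model should win in the large majority of datasets
        rng = np.random.default_rng(4)
        n = 800
        null_wins = 0
        for _ in range(10):
            X = pd.DataFrame(
                {
                    "temperature": rng.uniform(5, 25, n),
                    "wind_speed": rng.uniform(0, 20, n),
                    "dist_edge": rng.uniform(0, 200, n),
                }
            )
            y = rng.integers(0, 2, n)
            sel = StepwiseSelector(role="detection", use_gam=False).fit(X, y=y)
            null_wins += sel.selected_covariates_ == ()
        assert null_wins >= 6

    def test_true_effects_advance_and_win(self, campaign):
        table, _ = campaign
        sel = StepwiseSelector(role="false", use_gam=False).fit(table)
        assert "dist_edge" in sel.selected_covariates_
        assert sel.ranking_["aic"].is_monotonic_increasing

    def test_invariant_to_covariate_column_order(self):
        y, X = simulate_bernoulli_design("detection", 600, (6.5, -0.1879, -0.0233), SimulationConfig(seed=8))
        sel_a = StepwiseSelector(role="detection", use_gam=False).fit(X, y=y)
        sel_b = StepwiseSelector(role="detection", use_gam=False).fit(X[X.columns[::-1]], y=y)
        assert set(sel_a.selected_covariates_) == set(sel_b.selected_covariates_)
        assert sel_a.best_estimator_.aic_ == pytest.approx(sel_b.best_estimator_.aic_, abs=1e-8)

    def test_additive_needs_two_aic_points_to_displace_linear(self):
        # strictly linear truth: the GAM stage must not displace the GLM
        y, X = simulate_bernoulli_design("detection", 500, (1.0, -0.08, -0.01), SimulationConfig(seed=12))
        sel = StepwiseSelector(role="detection", use_gam=True).fit(X, y=y)
        gam_rows = sel.ranking_[sel.ranking_["model_type"] == "GAM"]
        if len(gam_rows):
            best_glm_aic = sel.ranking_[sel.ranking_["model_type"] == "GLM"]["aic"].min()
            if sel.selected_type_ == "GAM":
                assert best_glm_aic - gam_rows["aic"].min() > 2.0


class TestSerialization:
    def test_round_trip_preserves_predictions(self, campaign, tmp_path):
        table, _ = campaign
        y, X = build_response(table, "duplicate")
        fit = LogisticDetector(covariates=["dist_nearest"], role="duplicate").fit(X, y)
        path = tmp_path / "fit.yaml"
        save_fit(fit, path)
        back = load_fit(path)
        pd.testing.assert_frame_equal(back.predict_interval(X), fit.predict_interval(X))
        assert back.aic_ == pytest.approx(fit.aic_)

    def test_additive_fit_not_serializable(self, tmp_path):
        y, X = simulate_bernoulli_design("detection", 200, (1.0, -0.08, -0.01), SimulationConfig(seed=6))
        gam = AdditiveLogisticDetector(covariates=["temperature"]).fit(X, y)
        with pytest.raises(ValueError, match="additive"):
            save_fit(gam, tmp_path / "gam.yaml")
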