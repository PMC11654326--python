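"""Calibration regression, F-quantile band, paired bootstrap, reduction."""

import numpy as np
import pytest

import minlinmo as mm

# central-F quantiles frozen from an independent evaluation (R's qf)
QF_ORACLE = {
    (0.05, 676, 676): 0.88107172909644138,
    (0.95, 676, 676): 1.1349813720904676,
    (0.05, 436, 436): 0.85408859981696428,
    (0.95, 436, 436): 1.1708387165152487,
    (0.025, 10, 20): 0.29252223798395915,
    (0.975, 10, 20): 2.7736713751990809,
}


class TestCalibrationFit:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        fit = mm.calibration_fit(y, y)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.adjusted_r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)

    def test_rescaled_prediction_normalized(self):
        # predictions on twice the scale: calibration absorbs it, R2 stays 1
        rng = np.random.default_rng(1)
        y = rng.standard_normal(20)
        fit = mm.calibration_fit(y, 2 * y)
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        y = np.array([2.1, 1.9, 4.2, 3.7, 6.0, 5.5, 7.9, 8.1, 9.5, 9.8])
        fit = mm.calibration_fit(y, x)
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_constant_prediction_rejected(self):
        with pytest.raises(mm.ValidationError, match="constant"):
            mm.calibration_fit(np.arange(5.0), np.ones(5))


class TestFBounds:
    def test_reciprocal_symmetry(self):
        for d in (5, 50, 676):
            lo, hi = mm.f_bounds(0.05, d, d)
            assert lo == pytest.approx(1.0 / hi, rel=1e-12)

    def test_degenerate_limit_approaches_one(self):
        lo, hi = mm.f_bounds(0.05, 10**6, 10**6)
        assert lo == pytest.approx(1.0, abs=1e-2)
        assert hi == pytest.approx(1.0, abs=1e-2)

    @pytest.mark.parametrize("key", sorted(QF_ORACLE))
    def test_against_independent_quantile_oracle(self, key):
        q, d1, d2 = key
        if q < 0.5:
            value = mm.f_bounds(q, d1, d2)[0]
        else:
            value = mm.f_bounds(1 - q, d1, d2)[1]
        assert value == pytest.approx(QF_ORACLE[key], abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(mm.ValidationError):
            mm.f_bounds(0.05, 0, 10)
        with pytest.raises(mm.ValidationError):
            mm.f_bounds(0.7, 10, 10)


@pytest.fixture
def two_predictors():
    """A signal with two equally noisy predictors and one noise predictor."""
    rng = np.random.default_rng(12)
    n = 438
    truth = rng.standard_normal(n) * 10 + 280
    pred_a = truth + rng.standard_normal(n) * 3
    pred_b = truth + rng.standard_normal(n) * 3
    noise = rng.standard_normal(n) * 10 + 280
    return truth, pred_a, pred_b, noise


class TestPairedBootstrapF:
    def test_self_comparison_p_is_exactly_one(self, two_predictors):
        truth, pred_a, _, _ = two_predictors
        res = mm.paired_bootstrap_f(truth, pred_a, pred_a, B=1000, seed=0)
        np.testing.assert_array_equal(res.f_stats, 1.0)
        assert res.p_value == 1.0
        assert res.mean_f == 1.0

    def test_dof_derives_from_length(self, two_predictors):
        truth, pred_a, pred_b, _ = two_predictors
        res = mm.paired_bootstrap_f(truth, pred_a, pred_b, B=10, seed=0)
        assert res.dof == (436, 436)

    def test_good_vs_noise_is_significant(self):
        rng = np.random.default_rng(7)
        n = 400
        truth = rng.standard_normal(n)
        good = truth + 0.05 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        res = mm.paired_bootstrap_f(truth, good, noise, B=500, seed=1)
        assert res.p_value < 0.01
        assert res.mean_f < 1.0  # model a leaves far less residual variance
        # sanity oracle: the plain (non-bootstrap) variance-ratio F is far
        # outside the central band too
        fa = mm.calibration_fit(truth, good).residuals.var(ddof=1)
        fb = mm.calibration_fit(truth, noise).residuals.var(ddof=1)
        assert fa / fb < res.f_lower

    def test_equally_noisy_predictors_not_significant(self, two_predictors):
        truth, pred_a, pred_b, _ = two_predictors
        res = mm.paired_bootstrap_f(truth, pred_a, pred_b, B=1000, seed=3)
        assert res.p_value > 0.5

    def test_reciprocity_under_swap(self, two_predictors):
        truth, pred_a, pred_b, _ = two_predictors
        r_ab = mm.paired_bootstrap_f(truth, pred_a, pred_b, B=400, seed=5)
        r_ba = mm.paired_bootstrap_f(truth, pred_b, pred_a, B=400, seed=5)
        np.testing.assert_allclose(r_ba.f_stats, 1.0 / r_ab.f_stats, rtol=1e-12)
        assert r_ab.p_value == r_ba.p_value

    def test_seed_reproducibility(self, two_predictors):
        truth, pred_a, pred_b, _ = two_predictors
        r1 = mm.paired_bootstrap_f(truth, pred_a, pred_b, B=200, seed=42)
        r2 = mm.paired_bootstrap_f(truth, pred_a, pred_b, B=200, seed=42)
        np.testing.assert_array_equal(r1.f_stats, r2.f_stats)
        assert r1.p_value == r2.p_value

    def test_p_value_in_unit_interval(self, two_predictors):
        truth, pred_a, _, noise = two_predictors
        for seed in range(3):
            res = mm.paired_bootstrap_f(truth, pred_a, noise, B=50, seed=seed)
            assert 0.0 <= res.p_value <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(mm.ValidationError):
            mm.paired_bootstrap_f(np.ones(5), np.ones(5), np.ones(4))


class TestReduceModel:
    @pytest.fixture
    def fitted_on_planted(self):
        """Six-term model on test data where only two terms carry signal."""
        rng = np.random.default_rng(30)
        n, p = 400, 40
        vals = rng.standard_normal((n, p))
        y = 2.0 * vals[:, 0] - 1.5 * vals[:, 1] + 0.5 * rng.standard_normal(n)
        names = [f"x{i}" for i in range(p)]
        m = mm.PredictorMatrix(vals, names)
        yv = mm.OutcomeVector(y)
        fit = mm.fit_ols(vals[:, [0, 1, 5, 6, 7, 8]], y)
        model = mm.ModelSpec(
            intercept=fit.intercept,
            terms=[(names[j], float(b))
                   for j, b in zip([0, 1, 5, 6, 7, 8], fit.slopes)],
        )
        return model, m, yv

    def test_epsilon_zero_keeps_everything(self, fitted_on_planted):
        model, m, y = fitted_on_planted
        reduced = mm.reduce_model(model, m, y, epsilon=0.0)
        assert reduced.term_names == model.term_names

    def test_duplicate_term_dropped(self):
        rng = np.random.default_rng(31)
        n = 100
        vals = np.column_stack([rng.standard_normal(n)] * 1
                               + [rng.standard_normal(n)])
        vals = np.column_stack([vals, vals[:, 0]])  # column c duplicates a
        m = mm.PredictorMatrix(vals, ["a", "b", "c"])
        y = mm.OutcomeVector(vals[:, 0] + 0.5 * vals[:, 1]
                             + 0.2 * rng.standard_normal(n))
        model = mm.ModelSpec(intercept=0.0,
                             terms=[("a", 1.0), ("b", 0.5), ("c", 0.1)])
        reduced = mm.reduce_model(model, m, y, epsilon=0.01)
        assert reduced.term_names == ["a", "b"]

    def test_signal_terms_survive_at_default_epsilon(self, fitted_on_planted):
        model, m, y = fitted_on_planted
        reduced = mm.reduce_model(model, m, y, epsilon=0.01)
        assert reduced.term_names == ["x0", "x1"]

    def test_reduced_r2_close_to_full(self, fitted_on_planted):
        model, m, y = fitted_on_planted
        epsilon = 0.01
        reduced = mm.reduce_model(model, m, y, epsilon=epsilon)
        cols_full = [m.column_names.index(t) for t in model.term_names]
        cols_red = [m.column_names.index(t) for t in reduced.term_names]
        r2_full = mm.fit_ols(m.values[:, cols_full], y.values).r2
        r2_red = mm.fit_ols(m.values[:, cols_red], y.values).r2
        dropped = len(cols_full) - len(cols_red)
        assert r2_full - r2_red <= epsilon * dropped + 1e-12

    def test_missing_term_rejected(self, fitted_on_planted):
        model, m, y = fitted_on_planted
        bad = mm.ModelSpec(intercept=0.0, terms=[("nope", 1.0)])
        with pytest.raises(mm.ValidationError, match="nope"):
            mm.reduce_model(bad, m, y)
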