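"""LKB dose-response model, maximum-likelihood fit and validation metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rtrisk.ntcp import (
    LKBModel, auc, calibration_slope, fit_lkb, hosmer_lemeshow, invert_lkb,
    lkb_probability, scaled_brier, validate_predictions,
)


class TestLKBProbability:
    def test_half_probability_at_tv50(self):
        assert lkb_probability(15.07, 15.07, 0.62) == pytest.approx(0.5)

    def test_quarter_risk_threshold(self):
        # planning threshold: ~25% risk just below 8.8% lung volume
        assert lkb_probability(8.77, 15.07, 0.62) == pytest.approx(0.25, abs=2e-3)

    def test_zero_volume_risk(self):
        expected = stats.norm.cdf(-1.0 / 0.62)
        assert lkb_probability(0.0, 15.07, 0.62) == pytest.approx(expected)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.floats(1.0, 60.0), st.floats(0.05, 3.0),
        st.floats(0.0, 80.0), st.floats(0.01, 10.0),
    )
    def test_monotone_in_x_and_tv50(self, tv50, m, x, dx):
        p1 = lkb_probability(x, tv50, m)
        p2 = lkb_probability(x + dx, tv50, m)
        assert p2 >= p1
        p3 = lkb_probability(x, tv50 + 1.0, m)
        assert p3 <= p1 + 1e-15

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            lkb_probability(1.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            invert_lkb(0.5, 1.0, 0.0)


class TestInversion:
    def test_median_returns_tv50(self):
        assert invert_lkb(0.5, 15.07, 0.62) == pytest.approx(15.07)

    def test_quarter_risk_volume(self):
        assert invert_lkb(0.25, 15.07, 0.62) == pytest.approx(8.77, abs=5e-3)
        assert round(invert_lkb(0.25, 15.07, 0.62), 1) == 8.8

    def test_round_trip(self):
        for p in np.linspace(0.01, 0.99, 25):
            x = invert_lkb(p, 15.07, 0.62)
            assert lkb_probability(x, 15.07, 0.62) == pytest.approx(p, abs=1e-10)

    def test_bounds(self):
        with pytest.raises(ValueError):
            invert_lkb(0.0, 15.0, 0.6)
        with pytest.raises(ValueError):
            invert_lkb(1.0, 15.0, 0.6)


class TestFit:
    def test_beats_grid_search_oracle_small_n(self):
        x = np.array([2.0, 6.0, 10.0, 16.0, 22.0, 30.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        fit = fit_lkb(x, y, ci=False)
        tv_grid = np.linspace(0.5, 60.0, 200)
        m_grid = np.linspace(0.02, 5.0, 200)
        best = -np.inf
        for tv in tv_grid:
            p = stats.norm.cdf((x[None, :] - tv) / (m_grid[:, None] * tv))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = (y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=1)
            best = max(best, ll.max())
        assert fit.loglik >= best - 1e-9

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_lkb(np.full(20, 10.0), np.r_[np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError):
            fit_lkb(np.arange(10.0), np.zeros(10))

    def test_profile_ci_deviance_at_endpoints(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 35, 400)
        y = (rng.random(400) < lkb_probability(x, 15.07, 0.62)).astype(float)
        model = LKBModel().fit(x, y)
        bounds = [(1e-6, 10 * x.max()), (0.01, 10.0)]
        for idx, (lo, hi) in ((0, model.ci_tv50_), (1, model.ci_m_)):
            for v in (lo, hi):
                dev = model._profile_deviance(idx, v, x, y, bounds)
                assert dev == pytest.approx(3.841, abs=1e-3)
            est = (model.tv50_, model.m_)[idx]
            assert lo < est < hi

    def test_prediction_via_fixed_parameters(self):
        model = LKBModel(tv50=15.07, m=0.62)
        assert model.predict_proba([15.07])[0] == pytest.approx(0.5)
        assert model.invert(0.5) == pytest.approx(15.07)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.2, 0.8], [0, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.4] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pair_enumeration_oracle(self):
        pred = np.array([0.1, 0.4, 0.35, 0.8, 0.4])
        y = np.array([0, 0, 1, 1, 1])
        num, den = 0.0, 0
        for i, j in itertools.product(np.where(y == 1)[0], np.where(y == 0)[0]):
            den += 1
            if pred[i] > pred[j]:
                num += 1
            elif pred[i] == pred[j]:
                num += 0.5
        assert auc(pred, y) == pytest.approx(num / den)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        pred = rng.random(50)
        y = rng.integers(0, 2, 50)
        assert auc(pred, y) == pytest.approx(auc(np.exp(3 * pred), y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.4], [1, 1])


class TestHosmerLemeshow:
    def test_perfect_calibration_zero_statistic(self):
        # predictions exactly equal to group event rates
        pred = np.repeat([0.2, 0.5, 0.8], 10)
        y = np.concatenate([
            np.r_[np.ones(2), np.zeros(8)],
            np.r_[np.ones(5), np.zeros(5)],
            np.r_[np.ones(8), np.zeros(2)],
        ])
        stat, df, p = hosmer_lemeshow(pred, y, groups=3)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_group_hand_computation(self):
        pred = np.array([0.1, 0.1, 0.4, 0.4, 0.7, 0.7])
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 1.0])
        stat, df, p = hosmer_lemeshow(pred, y, groups=3)
        expected = 0.0
        for p_g, o_g, n_g in ((0.1, 1.0, 2), (0.4, 1.0, 2), (0.7, 2.0, 2)):
            e_g = n_g * p_g
            expected += (o_g - e_g) ** 2 / (e_g * (1 - e_g / n_g))
        assert stat == pytest.approx(expected, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-10)

    def test_null_distribution_of_p_values(self):
        # df = groups - 2 is calibrated for predictions refit on the same
        # data (the classic setting), so each replicate refits a logistic
        # model on the true linear predictor before grouping.
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            p0 = rng.uniform(0.05, 0.95, 250)
            lp = np.log(p0 / (1 - p0))
            y = (rng.random(250) < p0).astype(float)
            fit = sm.Logit(y, sm.add_constant(lp)).fit(disp=0)
            pred = np.asarray(fit.predict(sm.add_constant(lp)))
            pvals.append(hosmer_lemeshow(pred, y)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestBrierAndCalibration:
    def test_scaled_brier_reference_model_zero(self):
        y = np.array([0, 0, 1, 1.0])
        assert scaled_brier(np.full(4, y.mean()), y) == pytest.approx(0.0)

    def test_scaled_brier_perfect_one(self):
        y = np.array([0, 1, 0, 1.0])
        assert scaled_brier(y, y) == pytest.approx(1.0)

    def test_scaled_brier_hand_example(self):
        pred = np.array([0.2, 0.7, 0.3, 0.9])
        y = np.array([0.0, 1.0, 1.0, 1.0])
        bs = np.mean((pred - y) ** 2)
        ref = 0.75 * 0.25
        assert scaled_brier(pred, y) == pytest.approx(1 - bs / ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            scaled_brier([0.2, 0.4], [0, 0])

    def test_calibration_slope_self_consistency(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < pred).astype(float)
        slope, intercept = calibration_slope(pred, y)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_overconfident_predictions_halve_slope(self):
        rng = np.random.default_rng(7)
        pred = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < pred).astype(float)
        lp = np.log(pred / (1 - pred))
        over = 1 / (1 + np.exp(-2 * lp))  # doubled logits
        slope, _ = calibration_slope(over, y)
        assert slope == pytest.approx(0.5, abs=0.08)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope(np.full(20, 0.4), np.r_[np.ones(10), np.zeros(10)])


def test_validation_report_fields(medium_cohort):
    from rtrisk.cohort import factor_matrix

    X = factor_matrix(medium_cohort)
    y = np.array([int(p.rp_grade >= 1) for p in medium_cohort])
    model = LKBModel(ci=False).fit(X["IV40"], y)
    rep = validate_predictions(model.predict_proba(X["IV40"]), y)
    assert 0.5 < rep.auc <= 1.0
    assert rep.scaled_brier <= 1.0
    assert rep.hl_df == 8
    assert 0.5 < rep.calibration_slope < 2.0
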