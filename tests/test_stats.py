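"""Correlation, logistic regression, ROC/AUC and risk-model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lvshape as lv
from lvshape.shape_model import fit_ssm, score_matrix
from lvshape.stats import (compare_prediction_models, correlation_scan,
                           fit_logistic, loo_auc, pearson, roc_auc)
from lvshape.synthetic_data import orthogonal_field_population


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0, abs=1e-12)
        assert pearson(x, -x).r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        # covariance/SD formula: r = 10 / sqrt(10 * 14.8)
        assert res.r == pytest.approx(10.0 / np.sqrt(148.0), abs=1e-9)
        assert res.n == 5
        assert 0 < res.p_value <= 1

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    def test_matches_closed_form_and_symmetry(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r = pearson(x, y).r
        xc, yc = x - x.mean(), y - y.mean()
        closed = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(closed, abs=1e-12)
        assert pearson(y, x).r == pytest.approx(r, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestLogistic:
    def test_null_model(self):
        rng = np.random.default_rng(0)
        n = 2000
        X = rng.normal(size=(n, 2))
        y = np.repeat([0, 1], n // 2)
        rng.shuffle(y)
        m = fit_logistic(X, y)
        for j in (1, 2):
            assert abs(m.coefficients[j]) < 3 * m.standard_errors[j]
        assert abs(m.coefficients[0]) < 3 * m.standard_errors[0]
        assert m.status == "converged"

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(1)
        n = 5000
        X = rng.normal(size=(n, 2))
        eta = -1.0 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        m = fit_logistic(X, y)
        true = [-1.0, 0.8, -0.5]
        for j, b in enumerate(true):
            lo = m.coefficients[j] - 1.96 * m.standard_errors[j]
            hi = m.coefficients[j] + 1.96 * m.standard_errors[j]
            assert lo < b < hi
        # odds ratios and SC are consistent transforms of the coefficients
        np.testing.assert_allclose(m.odds_ratios, np.exp(m.coefficients))
        np.testing.assert_allclose(
            m.standardized_coefficients[1:],
            m.coefficients[1:] * X.std(axis=0, ddof=1))

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, atol=1e-4)

    def test_separation_flagged_and_penalized(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = [0, 0, 1, 1]
        m = fit_logistic(X, y)
        assert m.status == "penalized"
        assert np.all(np.isfinite(m.coefficients))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.zeros((10, 1)), np.ones(10))
        with pytest.raises(ValueError, match="support"):
            fit_logistic(np.random.default_rng(0).normal(size=(4, 5)),
                         [0, 1, 0, 1])

    def test_table_layout(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.5).astype(int)
        tbl = fit_logistic(X, y, ["age", "sv"]).table()
        assert list(tbl["parameter"]) == ["constant", "age", "sv"]
        assert (tbl["or_ci_low"] <= tbl["or_ci_high"]).all()


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_null_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_mann_whitney_oracle(self, seed, auc_oracle):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        scores = rng.integers(0, 6, n).astype(float)  # many ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == \
            pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == \
            pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * scores - 7, labels).auc == \
            pytest.approx(base, abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        curve = roc_auc(rng.normal(size=100), rng.integers(0, 2, 100))
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.one_minus_specificity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2, 0.3], [1, 1, 1])


class TestCorrelationScan:
    def test_scan_layout_and_constant_column_skipped(self):
        rng = np.random.default_rng(0)
        n = 30
        scores = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "mode1": rng.normal(size=n),
            "mode2": rng.normal(size=n),
        })
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "edv": scores["mode1"] * 2 + rng.normal(size=n),
            "flat": np.ones(n),
        })
        scan = correlation_scan(scores, cohort, ["edv", "flat"], phase="ED")
        assert set(scan["variable"]) == {"edv"}
        assert {"r", "p", "p_adjusted", "n"} <= set(scan.columns)
        strong = scan[(scan["mode"] == 1)].iloc[0]
        assert strong["r"] > 0.8


def _score_model_pair(rng, n, signal_col=None):
    """Fake ED/ES score tables + models from a field population."""
    base = rng.normal(scale=30.0, size=(15, 3))
    out = {}
    for phase, seed in (("ED", 1), ("ES", 2)):
        sets, _ = orthogonal_field_population(base, [6.0, 3.0], n,
                                              seed=seed, phase=phase)
        model = fit_ssm(sets, phase=phase)
        out[phase] = (score_matrix(model, sets), model)
    return out


class TestModelComparison:
    def _cohort(self, rng, n, scores, shape_driven):
        s1 = scores["mode1"].to_numpy()
        z = (s1 - s1.mean()) / s1.std(ddof=1)
        age = rng.normal(60, 10, n)
        if shape_driven:
            logit = 1.8 * z
        else:
            logit = 1.8 * (age - 60) / 10
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return pd.DataFrame({
            "subject_id": scores["subject_id"],
            "age": age,
            "sex": rng.choice(["M", "F"], n),
            "edv": rng.normal(80, 15, n).clip(40),
            "esv": rng.normal(30, 8, n).clip(5),
            "event": y,
        }).assign(esv=lambda d: np.minimum(d["esv"], d["edv"] - 5))

    def test_shape_driven_events_favor_shape_model(self):
        rng = np.random.default_rng(0)
        n = 80
        pair = _score_model_pair(rng, n)
        cohort = self._cohort(rng, n, pair["ED"][0], shape_driven=True)
        cmp = compare_prediction_models(cohort, pair["ED"][0], pair["ES"][0],
                                        pair["ED"][1], pair["ES"][1])
        assert cmp.shape_roc.auc > cmp.baseline_roc.auc
        assert 0 <= cmp.shape_loo_auc <= 1

    def test_demographic_events_do_not_favor_shape_model(self):
        wins = 0
        trials = 5
        for seed in range(trials):
            rng = np.random.default_rng(100 + seed)
            n = 80
            pair = _score_model_pair(rng, n)
            cohort = self._cohort(rng, n, pair["ED"][0], shape_driven=False)
            cmp = compare_prediction_models(
                cohort, pair["ED"][0], pair["ES"][0],
                pair["ED"][1], pair["ES"][1], compute_loo=False)
            if cmp.baseline_roc.auc >= cmp.shape_roc.auc - 0.05:
                wins += 1
        assert wins > trials / 2

    def test_empty_retained_fraction_rejected(self):
        rng = np.random.default_rng(0)
        pair = _score_model_pair(rng, 20)
        cohort = self._cohort(rng, 20, pair["ED"][0], shape_driven=True)
        with pytest.raises(ValueError):
            compare_prediction_models(cohort, pair["ED"][0], pair["ES"][0],
                                      pair["ED"][1], pair["ES"][1],
                                      retained_fraction=0.0)


def test_loo_auc_reasonable_on_strong_signal():
    rng = np.random.default_rng(0)
    n = 60
    x = rng.normal(size=(n, 1))
    y = (rng.random(n) < 1 / (1 + np.exp(-3 * x[:, 0]))).astype(int)
    assert loo_auc(x, y) > 0.8
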