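"""ROC curves, DeLong variance, Youden cutoffs and logistic panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from conftest import brute_force_u
from mirpanel import roc
from mirpanel.errors import InsufficientDataError
from mirpanel.groupstats import u_statistic


class TestEmpiricalRoc:
    def test_worked_example_with_tie(self):
        curve = roc.empirical_roc([1, 2, 3], [0, 1], polarity="higher_is_case")
        assert roc.auc(curve) == pytest.approx(5.5 / 6, abs=1e-12)

    def test_curve_invariants(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            case = rng.integers(0, 8, rng.integers(2, 15)).astype(float)
            control = rng.integers(0, 8, rng.integers(2, 15)).astype(float)
            curve = roc.empirical_roc(case, control)
            assert curve.fpr[0] == 0 and curve.tpr[0] == 0
            assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
            assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
            thr = curve.thresholds
            assert (np.diff(thr) < 0).all() or (np.diff(thr) > 0).all()

    def test_perfect_separation_and_degenerate(self):
        curve = roc.empirical_roc([5, 6], [1, 2], polarity="higher_is_case")
        assert roc.auc(curve) == 1.0
        assert any((f == 0 and t == 1) for f, t in zip(curve.fpr, curve.tpr))
        flat = roc.empirical_roc([3, 3], [3, 3])
        assert roc.auc(flat) == pytest.approx(0.5)

    def test_auto_polarity_flips_low_auc_scores(self):
        curve = roc.empirical_roc([1, 2], [5, 6])
        assert curve.polarity == "lower_is_case"
        assert roc.auc(curve) == 1.0

    def test_fixed_reversed_polarity_complements_auc(self):
        rng = np.random.default_rng(8)
        case, control = rng.normal(1, 1, 20), rng.normal(0, 1, 15)
        hi = roc.auc(roc.empirical_roc(case, control, "higher_is_case"))
        lo = roc.auc(roc.empirical_roc(case, control, "lower_is_case"))
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_auc_is_normalized_u(self):
        """Trapezoid area == U/(n1*n2) in the same orientation, near-exactly."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            case = rng.integers(0, 6, rng.integers(1, 20)).astype(float)
            control = rng.integers(0, 6, rng.integers(1, 20)).astype(float)
            a = roc.auc(roc.empirical_roc(case, control, "higher_is_case"))
            u = brute_force_u(case, control)
            assert abs(a - u / (len(case) * len(control))) <= 1e-12

    def test_empty_group(self):
        with pytest.raises(InsufficientDataError):
            roc.empirical_roc([], [1.0])


class TestDeLong:
    def test_perfect_separation_gives_zero_se(self):
        assert roc.delong_se([5, 6, 7], [1, 2, 3]) == 0.0

    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = np.array(["case"] * 15 + ["control"] * 15)
        delta, z, p = roc.delong_paired_test(scores, scores, labels)
        assert delta == 0.0 and z == 0.0 and p == 1.0

    def test_se_close_to_bootstrap(self):
        """DeLong SE within 15% of a 2,000-replicate bootstrap SE."""
        rng = np.random.default_rng(11)
        case = rng.normal(1.19, 1, 50)  # true AUC ~ 0.8
        control = rng.normal(0, 1, 50)
        se = roc.delong_se(case, control)
        boots = []
        for _ in range(2000):
            c = rng.choice(case, 50)
            k = rng.choice(control, 50)
            boots.append(u_statistic(c, k) / 2500)
        boot_se = np.std(boots, ddof=1)
        assert abs(se - boot_se) / boot_se < 0.15

    def test_paired_test_detects_dominant_marker(self):
        rng = np.random.default_rng(12)
        n = 80
        labels = np.array(["case"] * n + ["control"] * n)
        strong = np.r_[rng.normal(2, 1, n), rng.normal(0, 1, n)]
        weak = strong + rng.normal(0, 2.5, 2 * n)
        delta, z, p = roc.delong_paired_test(strong, weak, labels)
        assert delta > 0 and p < 0.05

    def test_too_small_groups(self):
        with pytest.raises(InsufficientDataError):
            roc.delong_se([1.0], [0.0, 0.5])


class TestConfidenceInterval:
    def test_zero_se_degenerates(self):
        assert roc.auc_confidence_interval(0.8, 0.0) == (0.8, 0.8)

    def test_symmetric_at_half(self):
        lo, hi = roc.auc_confidence_interval(0.5, 0.05)
        assert lo + hi == pytest.approx(1.0)

    def test_high_auc_interval_is_asymmetric(self):
        """At AUC 0.975 (SE 0.0181) the interval reaches down near 0.90 but
        stays well inside 1.0 — the asymmetry of the logit transform."""
        lo, hi = roc.auc_confidence_interval(0.975, 0.0181)
        assert 0.88 < lo < 0.93
        assert hi < 1.0
        assert (hi - 0.975) < (0.975 - lo)

    def test_boundary_auc_warns(self):
        with pytest.warns(UserWarning):
            assert roc.auc_confidence_interval(1.0, 0.01) == (1.0, 1.0)


class TestYouden:
    def test_tie_break_prefers_sensitivity(self):
        curve = roc.empirical_roc([2, 3, 4], [0, 1, 2], polarity="higher_is_case")
        cutoff, sens, spec, j = roc.youden_cutoff(curve)
        assert j == pytest.approx(2 / 3)
        assert sens == 1.0 and spec == pytest.approx(2 / 3)
        assert cutoff == 2.0

    def test_perfect_and_flat(self):
        perfect = roc.empirical_roc([5, 6], [1, 2], polarity="higher_is_case")
        assert roc.youden_cutoff(perfect)[3] == 1.0
        flat = roc.empirical_roc([3, 3], [3, 3])
        assert roc.youden_cutoff(flat)[3] == 0.0

    # 3-decimal grid keeps exp() strictly monotone in float64 (distinct
    # inputs stay distinct), which subnormal-scale floats would not
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 3)),
                 min_size=2, max_size=12),
        st.lists(st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 3)),
                 min_size=2, max_size=12),
    )
    def test_monotone_transform_invariance(self, case, control):
        """AUC and Youden J are rank statistics: exp() leaves them unchanged."""
        c1 = roc.empirical_roc(case, control, "higher_is_case")
        c2 = roc.empirical_roc(np.exp(case), np.exp(control), "higher_is_case")
        assert roc.auc(c1) == pytest.approx(roc.auc(c2), abs=1e-9)
        assert roc.youden_cutoff(c1)[3] == pytest.approx(roc.youden_cutoff(c2)[3], abs=1e-9)


class TestLogisticPanel:
    def make_data(self, seed=0, n=200, effects=(1.0, 1.0), noise=0):
        rng = np.random.default_rng(seed)
        cols = {}
        for i, eff in enumerate(effects):
            cols[f"m{i}"] = np.r_[rng.normal(eff, 1, n), rng.normal(0, 1, n)]
        for i in range(noise):
            cols[f"noise{i}"] = rng.normal(0, 1, 2 * n)
        labels = np.array(["case"] * n + ["control"] * n)
        return pd.DataFrame(cols), labels

    def test_single_marker_panel_reproduces_marker_roc(self):
        X, labels = self.make_data(seed=1, effects=(1.2,))
        model = roc.fit_logistic_panel(X, labels, ["m0"])
        marker_auc = roc.auc(
            roc.empirical_roc(X["m0"][labels == "case"], X["m0"][labels == "control"])
        )
        assert model.roc.auc == pytest.approx(marker_auc, abs=1e-12)

    def test_matches_statsmodels_mle(self):
        """IRLS coefficients agree with an independent ML fit."""
        import statsmodels.api as sm

        X, labels = self.make_data(seed=2, effects=(0.8, -0.6))
        model = roc.fit_logistic_panel(X, labels)
        y = (labels == "case").astype(float)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert list(model.coefficients.values()) == pytest.approx(ref.params[1:], abs=1e-6)

    def test_equal_effects_give_equal_slopes_and_better_auc(self):
        X, labels = self.make_data(seed=3, n=2000, effects=(1.0, 1.0))
        model = roc.fit_logistic_panel(X, labels)
        c0, c1 = model.coefficients["m0"], model.coefficients["m1"]
        assert c0 / c1 == pytest.approx(1.0, abs=0.25)
        for m in ("m0", "m1"):
            single = roc.fit_logistic_panel(X, labels, [m])
            assert model.roc.auc > single.roc.auc

    def test_separation_triggers_ridge_fallback(self):
        X = pd.DataFrame({"m0": np.r_[np.ones(10) * 3, np.zeros(10)]})
        labels = np.array(["case"] * 10 + ["control"] * 10)
        model = roc.fit_logistic_panel(X, labels)
        assert model.separation
        assert np.isfinite(model.intercept)
        assert all(np.isfinite(v) for v in model.coefficients.values())
        assert model.roc.auc == 1.0

    def test_missing_values_dropped_and_counted(self):
        X, labels = self.make_data(seed=4)
        X.loc[3, "m0"] = np.nan
        model = roc.fit_logistic_panel(X, labels)
        assert model.n_dropped == 1

    def test_sklearn_estimator_contract(self):
        clf = roc.PanelLogisticClassifier(ridge=1e-3)
        assert clone(clf).get_params()["ridge"] == 1e-3
        X, labels = self.make_data(seed=5)
        y = (labels == "case").astype(float)
        clf.fit(X.to_numpy(), y)
        proba = clf.predict_proba(X.to_numpy())
        assert proba.shape == (len(y), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(clf.predict(X.to_numpy())) <= {0.0, 1.0}


class TestSelectPanel:
    make_data = TestLogisticPanel.make_data

    def test_single_marker_selected(self):
        X, labels = self.make_data(seed=6, effects=(1.0,))
        model, trace = roc.select_panel(X, labels)
        assert trace["selected"] == ["m0"]

    def test_duplicated_marker_never_kept_twice(self):
        X, labels = self.make_data(seed=7, effects=(1.5,))
        X["copy"] = X["m0"]
        model, trace = roc.select_panel(X, labels)
        assert len(trace["selected"]) == 1

    def test_noise_markers_excluded_with_rationale(self):
        X, labels = self.make_data(seed=8, n=500, effects=(2.16, 1.63), noise=2)
        model, trace = roc.select_panel(X, labels)
        assert trace["selected"] == ["m0", "m1"]
        assert set(trace["excluded"]) == {"noise0", "noise1"}
        for info in trace["excluded"].values():
            assert abs(info["delta_auc_vs_selected"]) < 0.01

    def test_refuses_oversized_exhaustive_search(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 17)), columns=[f"m{i}" for i in range(17)])
        labels = np.array(["case"] * 15 + ["control"] * 15)
        with pytest.raises(ValueError, match="exhaustive"):
            roc.select_panel(X, labels)
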