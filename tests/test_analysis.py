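"""Tertiles, screening, multiple regression and group comparisons."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from neogrowth.analysis import (
    DeltaZModel,
    assign_tertiles,
    fit_multiple_regression,
    group_compare,
    paired_change_test,
    univariate_screen,
)


class TestTertiles:
    def test_nine_values_split_evenly(self):
        t = assign_tertiles(range(1, 10))
        assert list(t.labels) == [1, 1, 1, 2, 2, 2, 3, 3, 3]
        assert t.cut_lo <= t.cut_hi

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=30)
        perm = rng.permutation(30)
        t1 = assign_tertiles(values)
        t2 = assign_tertiles(values[perm])
        assert np.array_equal(t1.labels[perm], t2.labels)

    def test_tied_values_share_lower_label(self):
        t = assign_tertiles([1, 1, 2, 2, 3, 3])
        assert list(t.labels) == [1, 1, 2, 2, 3, 3]

    def test_labels_monotone_in_value(self, rng):
        values = rng.normal(size=50)
        labels = assign_tertiles(values).labels
        order = np.argsort(values)
        assert (np.diff(labels[order]) >= 0).all()

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            assign_tertiles([1.0, 2.0])
        with pytest.raises(ValueError, match="equal"):
            assign_tertiles([2.0, 2.0, 2.0, 2.0])


class TestScreen:
    def test_true_predictor_selected_noise_not(self, rng):
        n = 200
        x = rng.normal(size=n)
        cands = pd.DataFrame({"signal": x, "noise": rng.normal(size=n)})
        selected, pvals = univariate_screen(x.copy(), cands, alpha=0.10)
        assert "signal" in selected
        assert pvals["signal"] < 1e-10

    def test_alpha_one_is_a_no_op_filter(self, rng):
        cands = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        selected, _ = univariate_screen(rng.normal(size=50), cands, alpha=1.0)
        assert selected == list("abcd")

    def test_screen_monotone_in_alpha(self, rng):
        y = rng.normal(size=100)
        cands = pd.DataFrame(rng.normal(size=(100, 6)), columns=list("abcdef"))
        s_tight, _ = univariate_screen(y, cands, alpha=0.05)
        s_loose, _ = univariate_screen(y, cands, alpha=0.50)
        assert set(s_tight) <= set(s_loose)

    def test_constant_candidate_excluded(self, rng):
        cands = pd.DataFrame({"flat": np.ones(30), "ok": rng.normal(size=30)})
        selected, pvals = univariate_screen(rng.normal(size=30), cands, alpha=1.0)
        assert "flat" not in selected and "flat" not in pvals

    def test_null_selection_rate_matches_alpha(self, rng):
        """~alpha of pure-noise candidates pass the screen on average."""
        picks = 0
        reps, k = 40, 20
        for _ in range(reps):
            y = rng.normal(size=60)
            cands = pd.DataFrame(rng.normal(size=(60, k)))
            cands.columns = [f"c{i}" for i in range(k)]
            picks += len(univariate_screen(y, cands, alpha=0.10)[0])
        rate = picks / (reps * k)
        assert 0.05 < rate < 0.16  # binomial(800, 0.10) within ~4 sd


class TestMultipleRegression:
    def test_noiseless_line_recovered(self):
        x = np.arange(10.0)
        res = fit_multiple_regression(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.terms[0].coefficient == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.model_r2 == pytest.approx(1.0)

    def test_partial_r_squared_equals_simple_r2_single_predictor(self, rng):
        x = rng.integers(0, 2, size=80).astype(float)
        y = 0.5 * x + rng.normal(size=80)
        res = fit_multiple_regression(y, pd.DataFrame({"x": x}))
        simple_r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.terms[0].r_partial ** 2 == pytest.approx(simple_r2, rel=1e-9)
        assert np.sign(res.terms[0].r_partial) == np.sign(res.terms[0].coefficient)

    def test_residuals_orthogonal_to_predictors(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = X["a"].to_numpy() - 0.5 * X["b"].to_numpy() + rng.normal(size=60)
        res = fit_multiple_regression(y, X)
        fitted = res.intercept + X.to_numpy() @ np.array([t.coefficient for t in res.terms])
        resid = y - fitted
        for c in X.columns:
            assert abs(np.dot(resid, X[c])) < 1e-8

    def test_collinearity_named(self, rng):
        a = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=40)})
        with pytest.raises(ValueError, match="collinear"):
            fit_multiple_regression(rng.normal(size=40), X)

    def test_parameter_recovery_two_sd(self, rng):
        """Generating model (0.13/tertile step, -0.01/day) recovered at n=276."""
        n = 276
        tert = rng.integers(1, 4, size=n).astype(float)
        days = rng.normal(11.7, 6.9, size=n)
        y = -0.94 + 0.13 * tert - 0.01 * days + rng.normal(0, 0.45, size=n)
        res = fit_multiple_regression(y, pd.DataFrame({"tertile": tert, "days": days}))
        by_name = {t.name: t for t in res.terms}
        assert abs(by_name["tertile"].coefficient - 0.13) < 2 * by_name["tertile"].stderr
        assert abs(by_name["days"].coefficient + 0.01) < 2 * by_name["days"].stderr


class TestPairedAndGroups:
    def test_identical_vectors_degenerate(self):
        res = paired_change_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.mean_difference == 0.0 and res.pvalue == 1.0

    def test_constant_shift_detected(self, rng):
        before = rng.normal(0, 0.9, size=276)
        after = before - 0.8 + rng.normal(0, 0.45, size=276)
        res = paired_change_test(before, after)
        assert res.mean_difference == pytest.approx(-0.8, abs=0.1)
        assert res.pvalue < 1e-4

    def test_two_pairs_warns(self):
        with pytest.warns(UserWarning, match="n=2"):
            res = paired_change_test([1.0, 2.0], [2.0, 4.0])
        assert res.n == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            paired_change_test([1.0, 2.0], [1.0])

    def test_fisher_exact_p_matches_enumeration(self):
        """Perfectly separated 2x2: p is twice the single-table probability."""
        variable = [1] * 10 + [0] * 10
        groups = ["a"] * 10 + ["b"] * 10
        res = group_compare(variable, groups, categorical=True)
        assert res.test == "fisher_exact"
        assert res.pvalue == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_exact_path_chosen_on_sparse_table(self):
        variable = [1, 1, 0, 0, 0, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        assert group_compare(variable, groups, categorical=True).test == "fisher_exact"

    def test_chi2_on_large_table(self, rng):
        variable = rng.integers(0, 2, size=400)
        groups = rng.integers(0, 2, size=400)
        assert group_compare(variable, groups, categorical=True).test == "chi2"

    def test_continuous_dispatch(self, rng):
        v = rng.normal(size=60)
        g = ["a"] * 30 + ["b"] * 30
        assert group_compare(v, g, normal=True).test == "anova"
        assert group_compare(v, g, normal=False).test == "mannwhitneyu"
        g3 = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        assert group_compare(v, g3, normal=False).test == "kruskal"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "a"])


class TestDeltaZModel:
    def test_screen_then_fit_keeps_only_signal(self, rng):
        n = 150
        x = rng.normal(size=n)
        df = pd.DataFrame(
            {"y": 0.4 * x + rng.normal(0, 0.3, size=n), "x": x, "junk": rng.normal(size=n)}
        )
        res = DeltaZModel.from_dataframe(df, "y", ["x", "junk"], alpha=0.01).fit()
        assert res.selected == ["x"]
        assert res.params["x"] == pytest.approx(0.4, abs=0.1)
        assert "r_partial" in res.summary()

    def test_no_survivors_gives_intercept_only(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        res = DeltaZModel.from_dataframe(df, "y", ["x"], alpha=1e-6).fit()
        assert res.selected == [] and len(res.regression.terms) == 0
        assert res.regression.intercept == pytest.approx(df["y"].mean())

    def test_results_frame_shape(self, rng):
        n = 100
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["y", "a", "b"])
        df["y"] = df["a"] * 0.8 + rng.normal(0, 0.2, size=n)
        frame = DeltaZModel.from_dataframe(df, "y", ["a", "b"]).fit().to_frame()
        assert list(frame.columns) == ["variable", "coefficient", "r_partial", "p"]
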