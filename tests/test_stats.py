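"""Statistics oracles: design coding, OLS, Type-II F, correlations, refits.

Independent routes used as oracles: hand-built design matrices, the normal
equations, nested-model partial-F comparisons, the textbook Pearson formula,
and statsmodels' formula interface with its own Type-II ANOVA.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from braincohort.errors import (
    CollinearityError,
    DegenerateDesignError,
    ValidationError,
)
from braincohort.stats import (
    CohortModel,
    ModelSpec,
    build_design,
    correlation_matrix,
    fit_anova,
    fit_linear_model,
)


def frame_from(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"S{i:02d}" for i in range(1, n + 1)])


class TestBuildDesign:
    def test_single_numeric_regressor_two_columns(self):
        data = frame_from(y=[1.0, 2, 3, 4], x=[0.0, 1, 2, 3])
        d = build_design(data, ModelSpec("y", ("x",)))
        assert list(d.X.columns) == ["Intercept", "x"]

    def test_three_level_nominal_two_dummies(self):
        data = frame_from(y=[1.0] * 6, g=["a", "b", "c", "a", "b", "c"])
        d = build_design(data, ModelSpec("y", ("g",)))
        assert list(d.X.columns) == ["Intercept", "g[T.b]", "g[T.c]"]
        # reference = first sorted level 'a': rows for 'a' are all-zero dummies
        assert d.X.loc["S01", ["g[T.b]", "g[T.c]"]].tolist() == [0.0, 0.0]

    def test_interaction_matches_hand_built_matrix(self):
        """numeric x nominal(3) on a 9-row fixture vs an explicit matrix."""
        x = [1.0, 2, 3, 4, 5, 6, 7, 8, 9]
        g = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        data = frame_from(y=np.arange(9.0), x=x, g=g)
        d = build_design(data, ModelSpec("y", ("x", "g"),
                                         interactions=(("x", "g"),)))
        gb = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0.0])
        gc = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1.0])
        hand = np.column_stack([np.ones(9), np.asarray(x), gb, gc,
                                np.asarray(x) * gb, np.asarray(x) * gc])
        assert d.X.shape == (9, 6)
        assert np.array_equal(d.X.values, hand)

    def test_missing_rows_dropped_and_counted(self):
        data = frame_from(y=[1.0, np.nan, 3, 4], x=[0.0, 1, np.nan, 3])
        d = build_design(data, ModelSpec("y", ("x",)))
        assert len(d.y) == 2
        assert d.n_missing_excluded == 2

    def test_under_determined_rejected(self):
        data = frame_from(y=[1.0, 2], x=[0.0, 1], z=[3.0, 4])
        with pytest.raises(ValidationError):
            build_design(data, ModelSpec("y", ("x", "z")))

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec("y", ("x",), interactions=(("x", "g"),))


class TestOlsCore:
    def test_exact_line_perfect_fit(self):
        x = np.arange(10.0)
        data = frame_from(y=2 * x + 1, x=x)
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        assert fit.params["Intercept"] == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)
        assert np.allclose(fit.residuals.values, 0.0)
        assert fit.rsquared == pytest.approx(1.0)

    def test_coefficients_match_normal_equations(self, rng):
        """OLS vs (X'X)^{-1} X'y on random fixtures, < 1e-8."""
        for _ in range(5):
            n = 40
            data = frame_from(
                y=rng.normal(size=n),
                x1=rng.normal(size=n),
                x2=rng.normal(size=n),
                g=rng.choice(["p", "q"], size=n).tolist(),
            )
            spec = ModelSpec("y", ("x1", "x2", "g"),
                             interactions=(("x1", "g"),))
            fit = fit_linear_model(data, spec)
            X = fit.design.X.values
            beta = np.linalg.solve(X.T @ X, X.T @ fit.design.y.values)
            assert np.max(np.abs(fit.params.values - beta)) < 1e-8

    def test_nominal_only_fitted_values_are_group_means(self, rng):
        g = ["a"] * 7 + ["b"] * 5 + ["c"] * 8
        y = rng.normal(size=20) + [0 if v == "a" else 2 for v in g]
        data = frame_from(y=y, g=g)
        fit = fit_linear_model(data, ModelSpec("y", ("g",)))
        for level in "abc":
            rows = data.index[data.g == level]
            assert np.allclose(fit.fitted[rows],
                               data.loc[rows, "y"].mean())

    def test_residuals_sum_to_zero_with_intercept(self, rng):
        data = frame_from(y=rng.normal(size=25), x=rng.normal(size=25))
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        assert abs(fit.residuals.sum()) < 1e-8

    def test_collinear_design_names_aliased_term(self, rng):
        x = rng.normal(size=20)
        data = frame_from(y=rng.normal(size=20), x=x, x2=2 * x)
        with pytest.raises(CollinearityError, match="aliased terms.*x"):
            fit_linear_model(data, ModelSpec("y", ("x", "x2")))


class TestAnova:
    def test_balanced_one_way_f_equals_t_squared(self, rng):
        """For two balanced groups the one-way F equals the square of the
        pooled-variance two-sample t, computed from scratch."""
        a = rng.normal(0.0, 1.0, size=15)
        b = rng.normal(0.8, 1.0, size=15)
        data = frame_from(y=np.r_[a, b], g=["a"] * 15 + ["b"] * 15)
        fit = fit_anova(data, ModelSpec("y", ("g",)))
        F = fit.anova_table().loc["g", "F"]
        # from-scratch pooled t
        sp2 = (a.var(ddof=1) * 14 + b.var(ddof=1) * 14) / 28
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 15))
        assert F == pytest.approx(t ** 2, rel=1e-8)

    def test_constant_outcome_zero_f(self):
        data = frame_from(y=[3.0] * 12, g=["a", "b", "c"] * 4)
        fit = fit_anova(data, ModelSpec("y", ("g",)))
        assert fit.anova_table().loc["g", "sum_sq"] == pytest.approx(0.0,
                                                                     abs=1e-20)
        assert fit.anova_table().loc["g", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_type_ii_equals_nested_partial_f(self, rng):
        """Type-II F for each term == partial-F from nested SSE comparison
        built independently."""
        n = 36
        data = frame_from(
            y=rng.normal(size=n),
            x=rng.normal(size=n),
            g=rng.choice(["a", "b", "c"], size=n).tolist(),
        )
        spec = ModelSpec("y", ("x", "g"), interactions=(("x", "g"),))
        fit = fit_anova(data, spec)
        table = fit.anova_table()
        X, y = fit.design.X, fit.design.y.values

        def sse(cols):
            M = X[cols].values
            beta, *_ = np.linalg.lstsq(M, y, rcond=None)
            r = y - M @ beta
            return r @ r

        full_sse = sse(list(X.columns))
        mse = full_sse / fit.df_resid
        cases = {
            "x:g": (["Intercept", "x", "g[T.b]", "g[T.c]"],
                    list(X.columns)),
            "x": (["Intercept", "g[T.b]", "g[T.c]"],
                  ["Intercept", "x", "g[T.b]", "g[T.c]"]),
            "g": (["Intercept", "x"],
                  ["Intercept", "x", "g[T.b]", "g[T.c]"]),
        }
        for term, (reduced, fuller) in cases.items():
            df = len(fuller) - len(reduced)
            F = ((sse(reduced) - sse(fuller)) / df) / mse
            assert table.loc[term, "F"] == pytest.approx(F, rel=1e-10)

    def test_type_ii_matches_statsmodels_anova(self, rng):
        """Independent route: statsmodels formula fit + anova_lm(typ=2)."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        n = 45
        data = frame_from(
            y=rng.normal(size=n),
            x=rng.normal(size=n),
            g=rng.choice(["a", "b", "c"], size=n).tolist(),
        )
        fit = fit_anova(data, ModelSpec("y", ("x", "g"),
                                        interactions=(("x", "g"),)))
        sm_fit = smf.ols("y ~ x + C(g) + x:C(g)", data).fit()
        sm_table = anova_lm(sm_fit, typ=2)
        ours = fit.anova_table()
        assert ours.loc["x", "F"] == pytest.approx(sm_table.loc["x", "F"],
                                                   rel=1e-8)
        assert ours.loc["g", "F"] == pytest.approx(sm_table.loc["C(g)", "F"],
                                                   rel=1e-8)
        assert ours.loc["x:g", "F"] == pytest.approx(
            sm_table.loc["x:C(g)", "F"], rel=1e-8)

    def test_anova_and_lm_share_fit(self, rng):
        data = frame_from(y=rng.normal(size=20), x=rng.normal(size=20))
        spec = ModelSpec("y", ("x",))
        a = fit_anova(data, spec)
        b = fit_linear_model(data, spec)
        assert np.array_equal(a.fitted.values, b.fitted.values)
        assert np.array_equal(a.residuals.values, b.residuals.values)


class TestCorrelation:
    def test_self_correlation_and_perfect_line(self, rng):
        x = rng.normal(size=15)
        data = frame_from(x=x, y=-3 * x)
        r, n, p = correlation_matrix(data, ["x", "y"])
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert (n.values >= 15).all()

    def test_textbook_pearson_formula(self):
        x = np.array([1.0, 2, 4, 5, 8])
        y = np.array([2.0, 3, 5, 4, 9])
        data = frame_from(x=x, y=y)
        r, _, _ = correlation_matrix(data, ["x", "y"])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert abs(r.loc["x", "y"] - oracle) < 1e-12

    def test_pairwise_complete_and_small_n_undefined(self):
        data = frame_from(
            x=[1.0, 2, 3, 4, np.nan, 6],
            y=[2.0, 4, 6, np.nan, 10, 12],
            z=[1.0, np.nan, np.nan, np.nan, 5, np.nan],
        )
        r, n, p = correlation_matrix(data, ["x", "y", "z"])
        assert n.loc["x", "y"] == 4
        assert n.loc["x", "z"] == 1
        assert np.isnan(r.loc["x", "z"])
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_invariant_under_affine_rescaling(self, rng):
        data = frame_from(x=rng.normal(size=20), y=rng.normal(size=20))
        r1, _, _ = correlation_matrix(data, ["x", "y"])
        data2 = data.copy()
        data2["x"] = 100.0 - 7.0 * data2["x"]
        r2, _, _ = correlation_matrix(data2, ["x", "y"])
        assert r2.loc["x", "y"] == pytest.approx(-r1.loc["x", "y"])

    def test_symmetry_and_range(self, rng):
        data = frame_from(a=rng.normal(size=30), b=rng.normal(size=30),
                          c=rng.normal(size=30))
        r, _, _ = correlation_matrix(data, ["a", "b", "c"])
        assert np.allclose(r.values, r.values.T)
        assert (np.abs(r.values) <= 1.0 + 1e-12).all()

    def test_bh_adjustment_only_raises_pvalues(self, rng):
        data = frame_from(a=rng.normal(size=25), b=rng.normal(size=25),
                          c=rng.normal(size=25))
        _, _, raw = correlation_matrix(data, ["a", "b", "c"])
        _, _, adj = correlation_matrix(data, ["a", "b", "c"], bh_adjust=True)
        off = ~np.eye(3, dtype=bool)
        assert (adj.values[off] >= raw.values[off] - 1e-15).all()


class TestRefitExcluding:
    def test_empty_exclusion_is_identity(self, rng):
        data = frame_from(y=rng.normal(size=20), x=rng.normal(size=20))
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        refit = fit.refit_excluding([])
        assert np.array_equal(refit.params.values, fit.params.values)
        assert refit.subjects_used == fit.subjects_used

    def test_refit_equals_direct_reduced_fit(self, rng):
        """Excluding planted outliers == fitting the reduced sample
        directly; the original result is untouched."""
        n = 24
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(scale=0.3, size=n)
        y[-3:] = 40.0  # planted
        data = frame_from(y=y, x=x)
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        outliers = list(data.index[-3:])
        refit = fit.refit_excluding(outliers)
        direct = fit_linear_model(
            data.drop(index=outliers), ModelSpec("y", ("x",)))
        assert np.allclose(refit.params.values, direct.params.values)
        assert refit.n_outlier_excluded == 3
        assert fit.n_outlier_excluded == 0  # original untouched

    def test_exclusions_compose(self, rng):
        data = frame_from(y=rng.normal(size=15), x=rng.normal(size=15))
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        step = fit.refit_excluding(["S01"]).refit_excluding(["S02"])
        joint = fit.refit_excluding(["S01", "S02"])
        assert np.allclose(step.params.values, joint.params.values)
        assert step.n_outlier_excluded == joint.n_outlier_excluded == 2

    def test_excluding_a_whole_level_is_degenerate(self, rng):
        data = frame_from(y=rng.normal(size=9),
                          g=["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        fit = fit_anova(data, ModelSpec("y", ("g",)))
        with pytest.raises(DegenerateDesignError):
            fit.refit_excluding(["S01", "S02", "S03"])

    def test_unused_subject_rejected(self, rng):
        data = frame_from(y=rng.normal(size=10), x=rng.normal(size=10))
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        with pytest.raises(ValidationError):
            fit.refit_excluding(["ZZ99"])

    def test_correlation_flip_fixture(self, rng):
        """One planted leverage point masks a perfect correlation; removing
        it flips r from ~0 to > 0.9 and matches a direct reduced compute."""
        x = np.r_[rng.normal(size=12), 10.0]
        y = np.r_[x[:12] + rng.normal(scale=0.1, size=12), -1.2]
        data = frame_from(x=x, y=y)
        r_all, _, _ = correlation_matrix(data, ["x", "y"])
        r_reduced, _, _ = correlation_matrix(data, ["x", "y"],
                                             exclusions={"S13"})
        assert abs(r_all.loc["x", "y"]) < 0.5
        assert r_reduced.loc["x", "y"] > 0.9
        direct, _, _ = correlation_matrix(data.drop(index="S13"), ["x", "y"])
        assert r_reduced.loc["x", "y"] == pytest.approx(
            direct.loc["x", "y"])


class TestDiagnostics:
    def test_perfect_fit_zero_residuals(self):
        x = np.arange(8.0)
        data = frame_from(y=3 * x - 2, x=x)
        diag = fit_linear_model(data, ModelSpec("y", ("x",))
                                ).residual_diagnostics()
        assert np.allclose(diag.residuals.values, 0.0)

    def test_pairs_keyed_by_subject(self, rng):
        data = frame_from(y=rng.normal(size=12), x=rng.normal(size=12))
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        pairs = fit.residual_diagnostics().pairs()
        assert list(pairs.index) == list(fit.subjects_used)
        assert len(pairs) == fit.n_used

    def test_shapiro_w_high_under_normal_errors(self):
        """Standard-normal residuals, n=200: W > 0.95 in >= 95% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            y = 2 + x + rng.normal(size=200)
            data = frame_from(y=y, x=x)
            diag = fit_linear_model(data, ModelSpec("y", ("x",))
                                    ).residual_diagnostics()
            hits += diag.shapiro_w > 0.95
        assert hits >= 0.95 * n_seeds

    def test_too_few_points_unavailable(self):
        data = frame_from(y=[1.0, 2.0], x=[0.0, 1.0])
        fit = fit_linear_model(data, ModelSpec("y", ("x",)))
        with pytest.raises(ValidationError):
            fit.residual_diagnostics()


class TestModelFromDb:
    def test_nominal_decoding_and_sample_scoping(self, rng):
        from braincohort.cohortdb import CohortDB

        db = CohortDB()
        db.add_variable("score", "numeric")
        db.add_variable("grp", "nominal",
                        levels={1: "term", 2: "preterm"})
        subjects = [f"S{i:02d}" for i in range(1, 11)]
        db.set_values("score", {s: float(i) for i, s in enumerate(subjects)})
        db.set_values("grp", {s: 1 if i < 5 else 2
                              for i, s in enumerate(subjects)})
        db.create_sample("first8", subjects[:8])
        model = CohortModel.from_db(db, ModelSpec("score", ("grp",)),
                                    sample_name="first8")
        fit = model.fit()
        assert fit.n_used == 8
        assert "grp[T.term]" in fit.params.index or \
            "grp[T.preterm]" in fit.params.index

    def test_summary_mentions_key_numbers(self, rng):
        data = frame_from(y=rng.normal(size=10), x=rng.normal(size=10))
        text = fit_linear_model(data, ModelSpec("y", ("x",))).summary()
        assert "R-squared" in text and "Type-II ANOVA" in text
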