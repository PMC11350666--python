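"""Canonical discriminant analysis, stepwise selection and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cormorant_sexing as cs
from cormorant_sexing.discriminant_analysis import DiscriminantModel
from cormorant_sexing.errors import (
    CollinearityError,
    EmptyModelError,
    IncompleteRecordError,
    InsufficientDataError,
)


def _two_group_data(rng, n_f=120, n_m=150, delta=(1.0, 0.6), rho=0.4, k=2):
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    Xf = rng.multivariate_normal(np.zeros(k), cov, n_f)
    Xm = rng.multivariate_normal(np.asarray(delta)[:k], cov, n_m)
    X = np.vstack([Xf, Xm])
    y = np.array(["F"] * n_f + ["M"] * n_m)
    return X, y


class TestFitLda:
    def test_one_dimensional_closed_form(self, rng):
        """1-D LDA: b = 1/s_pooled, score separation = sample Mahalanobis."""
        f = rng.normal(0, 1, 80)
        m = rng.normal(1, 1, 50)
        X = np.concatenate([f, m])[:, None]
        y = np.array(["F"] * 80 + ["M"] * 50)
        model = cs.fit_lda(X, y, variables=["x"])
        s = np.sqrt((79 * f.var(ddof=1) + 49 * m.var(ddof=1)) / 128)
        assert model.coefficients[0] == pytest.approx(1 / s, rel=1e-10)
        sep = model.score_means["M"] - model.score_means["F"]
        assert sep == pytest.approx((m.mean() - f.mean()) / s, rel=1e-10)

    def test_model_invariants(self, rng):
        X, y = _two_group_data(rng)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        scores = model.score(X)
        # male-positive orientation
        assert model.score_means["M"] > model.score_means["F"]
        # size-weighted overall mean score 0
        assert scores.mean() == pytest.approx(0.0, abs=1e-8)
        # pooled within-group score variance 1
        sf, sm = scores[y == "F"], scores[y == "M"]
        pooled = ((len(sf) - 1) * sf.var(ddof=1)
                  + (len(sm) - 1) * sm.var(ddof=1)) / (len(scores) - 2)
        assert pooled == pytest.approx(1.0, abs=1e-8)
        assert 0 < model.wilks_lambda <= 1

    def test_no_separation_gives_lambda_one(self, rng):
        X = rng.normal(0, 1, (200, 2))
        y = np.array(["F", "M"] * 100)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        assert model.wilks_lambda > 0.97
        assert abs(model.score_means["M"] - model.score_means["F"]) < 0.3

    def test_published_sign_structure_on_wing_bill(self, small_sample):
        """Wing and bill coefficients both positive, as in the printed D2."""
        model = cs.fit_lda(small_sample.data,
                           variables=["wing_length", "bill_length"])
        assert (model.coefficients > 0).all()

    def test_standardized_coefficients_scale_free(self, rng):
        X, y = _two_group_data(rng)
        m1 = cs.fit_lda(X, y, variables=["a", "b"])
        X2 = X.copy()
        X2[:, 0] *= 10.0  # cm -> mm style rescale
        m2 = cs.fit_lda(X2, y, variables=["a", "b"])
        assert m2.coefficients[0] == pytest.approx(m1.coefficients[0] / 10, rel=1e-8)
        np.testing.assert_allclose(m2.std_coefficients, m1.std_coefficients,
                                   rtol=1e-8)
        np.testing.assert_allclose(m2.score(X2), m1.score(X), atol=1e-8)
        assert m2.wilks_lambda == pytest.approx(m1.wilks_lambda, rel=1e-10)

    def test_row_permutation_invariance(self, rng):
        X, y = _two_group_data(rng)
        perm = rng.permutation(len(y))
        m1 = cs.fit_lda(X, y, variables=["a", "b"])
        m2 = cs.fit_lda(X[perm], y[perm], variables=["a", "b"])
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, rtol=1e-9)
        assert m1.constant == pytest.approx(m2.constant, rel=1e-9)

    def test_collinear_variables_rejected(self, rng):
        x = rng.normal(0, 1, 100)
        X = np.column_stack([x, 2 * x])
        y = np.array(["F"] * 50 + ["M"] * 50)
        with pytest.raises(CollinearityError):
            cs.fit_lda(X, y, variables=["a", "b"])

    def test_too_few_cases_rejected(self):
        X = np.array([[1.0], [2.0], [3.0]])
        with pytest.raises(InsufficientDataError):
            cs.fit_lda(X, np.array(["F", "M", "M"]), variables=["a"])

    def test_serialization_round_trip_bit_exact(self, rng):
        X, y = _two_group_data(rng)
        m1 = cs.fit_lda(X, y, variables=["a", "b"])
        m2 = DiscriminantModel.from_json(m1.to_json())
        assert m2.to_json() == m1.to_json()
        assert m2.constant == m1.constant
        assert (m2.coefficients == m1.coefficients).all()
        assert (m2.pooled_cov == m1.pooled_cov).all()

    def test_agrees_with_sklearn_reference(self, rng):
        """Independent cross-check: equal-prior sklearn LDA predictions."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        X, y = _two_group_data(rng, n_f=200, n_m=260)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        ours = cs.classify_sample(model, X)["predicted"].to_numpy()
        ref = sklearn_lda(priors=[0.5, 0.5]).fit(X, y).predict(X)
        assert (ours == ref).all()


class TestWilksLambda:
    def test_univariate_anova_identity(self, rng):
        """lambda = 1 / (1 + t^2/df) for one variable."""
        f, m = rng.normal(0, 1, 40), rng.normal(0.8, 1, 55)
        X = np.concatenate([f, m])[:, None]
        y = np.array(["F"] * 40 + ["M"] * 55)
        lam = cs.wilks_lambda(X, y)
        t = cs.two_sample_t(m, f)
        assert lam == pytest.approx(1 / (1 + t.statistic**2 / t.df[0]), rel=1e-10)

    def test_two_variable_toy_determinant_ratio(self):
        X = np.array([
            [1.0, 2.0], [2.0, 1.0], [3.0, 3.0],   # F
            [4.0, 5.0], [5.0, 3.0], [6.0, 6.0],   # M
        ])
        y = np.array(["F", "F", "F", "M", "M", "M"])
        # brute-force W and T
        T = (X - X.mean(0)).T @ (X - X.mean(0))
        W = np.zeros((2, 2))
        for g in ("F", "M"):
            Xg = X[y == g]
            W += (Xg - Xg.mean(0)).T @ (Xg - Xg.mean(0))
        expected = np.linalg.det(W) / np.linalg.det(T)
        assert cs.wilks_lambda(X, y) == pytest.approx(expected, rel=1e-12)

    def test_permuted_labels_near_one(self, rng):
        X, y = _two_group_data(rng, n_f=500, n_m=500)
        lam = cs.wilks_lambda(X, rng.permutation(y))
        assert lam > 0.98

    def test_weakly_decreasing_in_added_variables(self, rng):
        X, y = _two_group_data(rng, delta=(1.0, 0.6, 0.0), k=3)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        lam1 = cs.wilks_lambda(df[["a"]].to_numpy(), y)
        lam2 = cs.wilks_lambda(df[["a", "b"]].to_numpy(), y)
        lam3 = cs.wilks_lambda(df[["a", "b", "c"]].to_numpy(), y)
        assert lam1 >= lam2 >= lam3


class TestPartialF:
    def test_no_contribution_is_zero(self):
        assert cs.partial_F(0.5, 0.5, n=100, p=2) == 0.0

    def test_hand_evaluated_formula(self):
        assert cs.partial_F(0.5, 0.6, n=100, g=2, p=3) == pytest.approx(19.2)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            cs.partial_F(0.7, 0.5, n=100, p=2)

    def test_equals_squared_partial_regression_t(self, rng):
        """Entering variable's partial F = squared t of that variable in the
        regression of the group code on included + candidate variables."""
        X, y = _two_group_data(rng, n_f=60, n_m=70, delta=(0.8, 0.5))
        code = np.where(y == "M", 1.0, -1.0)
        lam_without = cs.wilks_lambda(X[:, [0]], y)
        lam_with = cs.wilks_lambda(X, y)
        f = cs.partial_F(lam_with, lam_without, n=len(y), p=2)
        # OLS with intercept; oracle via lstsq + classic t-statistic
        A = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(A, code, rcond=None)
        resid = code - A @ beta
        s2 = resid @ resid / (len(y) - A.shape[1])
        cov = s2 * np.linalg.inv(A.T @ A)
        t_cand = beta[2] / np.sqrt(cov[2, 2])
        assert f == pytest.approx(t_cand**2, rel=1e-9)


class TestBackwardStepwise:
    def test_single_strong_variable_retained(self, rng):
        f, m = rng.normal(0, 1, 200), rng.normal(3, 1, 200)
        df = pd.DataFrame({"x": np.concatenate([f, m])})
        y = np.array(["F"] * 200 + ["M"] * 200)
        model, trace = cs.backward_stepwise(df, y, candidates=["x"])
        assert model.variables == ("x",)
        direct = cs.fit_lda(df[["x"]].to_numpy(), y, variables=["x"])
        assert model.coefficients[0] == pytest.approx(direct.coefficients[0])
        assert trace == []

    def test_noise_variable_removed(self):
        """A variable with no group effect and no correlation with the
        informative variables is dropped (typical, null-F < 2.71 case)."""
        rng = np.random.default_rng(0)
        cov = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]])
        X = np.vstack([
            rng.multivariate_normal([0, 0, 0], cov, 400),
            rng.multivariate_normal([1.0, 0.8, 0.0], cov, 400),
        ])
        y = np.array(["F"] * 400 + ["M"] * 400)
        df = pd.DataFrame(X, columns=["wing", "bill", "noise"])
        model, trace = cs.backward_stepwise(df, y)
        assert set(model.variables) == {"wing", "bill"}
        assert trace[0]["variable"] == "noise"
        assert trace[0]["direction"] == "remove"

    def test_correlated_suppressor_variable_retained(self):
        """A variable with zero mean difference but strong correlation to an
        informative variable improves conditional discrimination (suppressor)
        and is legitimately kept by the partial-F criterion."""
        rng = np.random.default_rng(1)
        cov = np.full((3, 3), 0.6) + 0.4 * np.eye(3)
        X = np.vstack([
            rng.multivariate_normal([0, 0, 0], cov, 1000),
            rng.multivariate_normal([1.0, 0.8, 0.0], cov, 1000),
        ])
        y = np.array(["F"] * 1000 + ["M"] * 1000)
        df = pd.DataFrame(X, columns=["wing", "bill", "supp"])
        model, _ = cs.backward_stepwise(df, y)
        assert "supp" in model.variables

    def test_terminal_state_conditions_vs_enumeration(self, rng):
        """Final set: every included F >= f_remove, every excluded F < f_enter,
        with lambdas recomputed from scratch over all subsets."""
        X, y = _two_group_data(rng, n_f=300, n_m=300,
                               delta=(1.0, 0.6, 0.3, 0.0), k=4)
        names = ["a", "b", "c", "d"]
        df = pd.DataFrame(X, columns=names)
        model, _ = cs.backward_stepwise(df, y, candidates=names)
        final = set(model.variables)
        n = len(y)

        def lam(subset):
            return cs.wilks_lambda(df[sorted(subset)].to_numpy(), y)

        for v in final:
            f = cs.partial_F(lam(final), lam(final - {v}) if len(final) > 1
                             else 1.0, n, p=len(final))
            assert f >= 2.71
        for v in set(names) - final:
            f = cs.partial_F(lam(final | {v}), lam(final), n, p=len(final) + 1)
            assert f < 3.84

    def test_noise_removal_rate_matches_null_theory(self):
        """A variable with no group effect has a null-F(1, n-3) partial F, so
        it survives removal (F >= 2.71) with probability ~0.10: the observed
        removal count over 100 replicates must sit in the binomial 99% CI
        around P(F < 2.71) = 0.900."""
        removed = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            cov = np.array([[1.0, 0.5, 0.0],
                            [0.5, 1.0, 0.0],
                            [0.0, 0.0, 1.0]])
            X = np.vstack([
                rng.multivariate_normal([0, 0, 0], cov, 2000),
                rng.multivariate_normal([0.9, 0.6, 0.0], cov, 2000),
            ])
            y = np.array(["F"] * 2000 + ["M"] * 2000)
            df = pd.DataFrame(X, columns=["wing", "bill", "noise"])
            model, _ = cs.backward_stepwise(df, y)
            if set(model.variables) == {"wing", "bill"}:
                removed += 1
        p = stats.f.cdf(2.71, 1, 3997)
        lo, hi = stats.binom.ppf([0.005, 0.995], 100, p)
        assert lo <= removed <= hi

    def test_all_variables_removed_raises_with_trace(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (100, 2))
        y = np.array(["F", "M"] * 50)
        df = pd.DataFrame(X, columns=["a", "b"])
        with pytest.raises(EmptyModelError) as exc:
            cs.backward_stepwise(df, y)
        assert len(exc.value.trace) == 2


class TestClassification:
    def test_record_at_male_centroid(self, rng):
        X, y = _two_group_data(rng)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        out = cs.classify(model, dict(zip(["a", "b"], model.centroids["M"])))
        assert out.predicted == "M"
        assert out.posteriors["M"] > 0.5
        assert out.d2["M"] == pytest.approx(0.0, abs=1e-10)
        assert sum(out.posteriors.values()) == pytest.approx(1.0)

    def test_midpoint_is_equivocal(self, rng):
        X, y = _two_group_data(rng)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        mid = (model.centroids["M"] + model.centroids["F"]) / 2
        out = cs.classify(model, dict(zip(["a", "b"], mid)))
        assert out.posteriors["M"] == pytest.approx(0.5, abs=1e-9)

    def test_missing_variable_named(self, rng):
        X, y = _two_group_data(rng)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        with pytest.raises(IncompleteRecordError, match="b"):
            cs.classify(model, {"a": 1.0, "b": np.nan})

    def test_equivalent_to_canonical_midpoint_rule(self, rng):
        """Mahalanobis/equal-priors prediction = cut at the midpoint of the
        group score means on the canonical axis, for every case."""
        X, y = _two_group_data(rng, n_f=400, n_m=600)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        pred = cs.classify_sample(model, X)["predicted"].to_numpy()
        cut = (model.score_means["M"] + model.score_means["F"]) / 2
        rule = np.where(model.score(X) > cut, "M", "F")
        assert (pred == rule).all()

    def test_classify_sample_matches_classify(self, rng):
        X, y = _two_group_data(rng, n_f=30, n_m=30)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        table = cs.classify_sample(model, X)
        for i in (0, 17, 59):
            single = cs.classify(model, dict(zip(["a", "b"], X[i])))
            assert single.predicted == table["predicted"].iloc[i]
            assert single.posteriors["M"] == pytest.approx(
                table["post_M"].iloc[i], rel=1e-10
            )


class TestResubstitutionAccuracy:
    def test_separable_groups_perfect(self):
        X = np.concatenate([np.zeros(20), np.full(20, 100.0)])[:, None]
        X = X + np.linspace(0, 1, 40)[:, None]  # avoid zero variance
        y = np.array(["F"] * 20 + ["M"] * 20)
        df = pd.DataFrame({"x": X[:, 0], "sex": y})
        model = cs.fit_lda(df, variables=["x"])
        acc = cs.resubstitution_accuracy(model, df)
        assert acc["male_pct"] == acc["female_pct"] == acc["overall_pct"] == 100.0

    def test_overall_is_case_weighted_mean(self, rng):
        X, y = _two_group_data(rng, n_f=70, n_m=130)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["sex"] = y
        model = cs.fit_lda(df, variables=["a", "b"])
        acc = cs.resubstitution_accuracy(model, df)
        expected = (acc["n_m"] * acc["male_pct"] + acc["n_f"] * acc["female_pct"]) \
            / (acc["n_m"] + acc["n_f"])
        assert acc["overall_pct"] == pytest.approx(expected, abs=1e-12)

    def test_parameter_recovery_direction(self):
        """Fitted discriminant direction within 5 degrees of the population
        direction Sigma^-1 (mu_M - mu_F) at n=5000/sex."""
        rng = np.random.default_rng(314)
        rho = 0.5
        cov = np.array([[1.0, rho], [rho, 1.0]])
        delta = np.array([1.0, 0.5])
        Xf = rng.multivariate_normal([0, 0], cov, 5000)
        Xm = rng.multivariate_normal(delta, cov, 5000)
        X = np.vstack([Xf, Xm])
        y = np.array(["F"] * 5000 + ["M"] * 5000)
        model = cs.fit_lda(X, y, variables=["a", "b"])
        true_dir = np.linalg.solve(cov, delta)
        cosine = model.coefficients @ true_dir / (
            np.linalg.norm(model.coefficients) * np.linalg.norm(true_dir)
        )
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 5.0
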