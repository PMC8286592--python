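"""One-class Mahalanobis detector and mixed-effects logistic classifier."""

import numpy as np
import pandas as pd
import pytest

from resppat.classify import (
    ClassifyConfig,
    ReferenceFitError,
    ReferenceModel,
    build_fold_plan,
    fit_mixed_logistic,
    fit_reference,
    mahalanobis_score,
    one_class_cv,
    run_one_class,
    shrunk_covariance,
    supervised_cv,
)
from resppat.evaluate import auc_trapezoid, roc_curve


def _subject_table(n_ref=20, n_ex=4, shift=2.0, seed=0, subject="S1"):
    rng = np.random.default_rng(seed)
    n = n_ref + n_ex
    return pd.DataFrame({
        "subject": [subject] * n,
        "window": np.arange(n),
        "label": ["reference"] * n_ref + ["exercise"] * n_ex,
        "quality": "ok",
        "breathing_rate": np.r_[rng.normal(0.25, 0.03, n_ref),
                                rng.normal(0.25 + 0.03 * shift, 0.03, n_ex)],
        "amplitude": np.r_[rng.normal(1.0, 0.1, n_ref),
                           rng.normal(1.0 + 0.1 * shift, 0.1, n_ex)],
    })


class TestShrunkCovariance:
    def test_duplicated_feature_gives_positive_definite(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0]])  # exact duplicate -> singular S
        sigma, lam = shrunk_covariance(X)
        assert lam >= 1e-3
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_intensity_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for n in (10, 100):
            _, lam = shrunk_covariance(rng.normal(size=(n, 4)))
            assert 1e-3 <= lam <= 1.0

    def test_explicit_intensity_respected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        S = np.cov(X.T, ddof=1)
        sigma, lam = shrunk_covariance(X, shrinkage=0.5)
        assert lam == 0.5
        expected = 0.5 * S + 0.5 * np.diag(np.diag(S))
        np.testing.assert_allclose(sigma, expected, atol=1e-10)

    def test_intensity_vanishes_for_truly_correlated_data(self):
        """With genuine correlation the data-driven intensity goes to
        zero as the sample grows (the raw covariance is already right)."""
        rng = np.random.default_rng(3)
        C = np.array([[1.0, 0.7], [0.7, 1.0]])
        small = rng.multivariate_normal([0, 0], C, size=15)
        big = rng.multivariate_normal([0, 0], C, size=5000)
        _, lam_small = shrunk_covariance(small)
        _, lam_big = shrunk_covariance(big)
        assert lam_big < lam_small
        assert lam_big < 0.05


class TestMahalanobis:
    def _model(self, mean, cov):
        return ReferenceModel(np.asarray(mean, float), np.asarray(cov, float),
                              0.0, ["a", "b"][: len(mean)])

    def test_euclidean_case(self):
        m = self._model([0, 0], np.eye(2))
        assert mahalanobis_score(m, np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_zero_at_mean(self):
        m = self._model([1.5, -2.0], [[2.0, 0.3], [0.3, 1.0]])
        assert mahalanobis_score(m, np.array([1.5, -2.0])) == pytest.approx(0.0)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            d = int(rng.integers(1, 6))
            A = rng.normal(size=(d + 4, d))
            cov = A.T @ A / len(A) + 0.05 * np.eye(d)
            mu = rng.normal(size=d)
            x = rng.normal(size=d)
            m = ReferenceModel(mu, cov, 0.0, [f"f{i}" for i in range(d)])
            oracle = np.sqrt((x - mu) @ np.linalg.inv(cov) @ (x - mu))
            assert mahalanobis_score(m, x) == pytest.approx(oracle, abs=1e-10)

    def test_missing_values_score_nan(self):
        m = self._model([0, 0], np.eye(2))
        assert np.isnan(mahalanobis_score(m, np.array([np.nan, 1.0])))

    def test_affine_invariance(self):
        """With raw covariance (no shrinkage), distances are invariant
        under invertible affine maps applied to train and test jointly."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.normal(size=(60, 3)) @ np.diag([1.0, 2.0, 0.5])
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            b = rng.normal(size=3)
            cols = ["breathing_rate", "amplitude", "arima_mu"]
            x = rng.normal(size=3)
            m1 = ReferenceModel(X.mean(0), shrunk_covariance(X, 0.0)[0], 0.0,
                                cols)
            m2 = ReferenceModel((X @ A + b).mean(0),
                                shrunk_covariance(X @ A + b, 0.0)[0], 0.0,
                                cols)
            d1 = mahalanobis_score(m1, x)
            d2 = mahalanobis_score(m2, x @ A + b)
            assert d1 == pytest.approx(d2, rel=1e-8)


class TestFitReference:
    def test_one_dimensional_reduces_to_mean_variance(self):
        df = _subject_table()
        ref = df[df.label == "reference"]
        m = fit_reference(ref, "rate")
        assert m.mean.shape == (1,)
        assert m.covariance.shape == (1, 1)
        assert m.covariance[0, 0] == pytest.approx(
            ref["breathing_rate"].var(ddof=1), rel=0.01
        )

    def test_gaussian_mean_recovery(self):
        rng = np.random.default_rng(6)
        true_mean = np.array([0.3, 1.2])
        X = rng.multivariate_normal(true_mean, np.diag([0.01, 0.04]), size=500)
        df = pd.DataFrame(X, columns=["breathing_rate", "amplitude"])
        m = fit_reference(df, "rate+amplitude")
        se = np.sqrt(np.diag(m.covariance) / 500)
        assert np.all(np.abs(m.mean - true_mean) < 3 * se)

    def test_too_few_rows_identifies_subject(self):
        df = _subject_table(n_ref=3)
        with pytest.raises(ReferenceFitError, match="S1"):
            fit_reference(df[df.label == "reference"], "rate+amplitude",
                          subject_id="S1", fold=2)


class TestOneClassCv:
    def test_healthy_scheme_prediction_counts(self):
        """20 reference + 4 exercise windows: one prediction per reference
        point, five per exercise point."""
        df = _subject_table(n_ref=20, n_ex=4)
        plan = build_fold_plan(20, 4, "healthy")
        scored = one_class_cv(df, "rate+amplitude", plan)
        ref = scored[scored.label == "reference"]
        ex = scored[scored.label == "exercise"]
        assert len(ref) == 20
        assert len(ex) == 20  # 4 windows x 5 folds
        assert ex.groupby("window").size().eq(5).all()

    def test_copd_scheme_one_prediction_per_point(self):
        df = _subject_table(n_ref=40, n_ex=15)
        plan = build_fold_plan(40, 15, "copd")
        scored = one_class_cv(df, "rate+amplitude", plan)
        assert len(scored) == 55
        assert scored.groupby("window").size().eq(1).all()

    def test_insufficient_reference_windows_skipped(self, caplog):
        df = _subject_table(n_ref=5, n_ex=4)
        out = run_one_class(df, "rate", "healthy")
        assert out.empty

    def test_null_distribution_auc_near_half(self):
        """Reference and exercise drawn from the same distribution give
        chance-level separation on average."""
        aucs = []
        for seed in range(40):
            df = _subject_table(n_ref=20, n_ex=4, shift=0.0, seed=seed)
            plan = build_fold_plan(20, 4, "healthy")
            scored = one_class_cv(df, "rate+amplitude", plan)
            fpr, tpr, _ = roc_curve(scored["score"],
                                    scored["label"] == "exercise")
            aucs.append(auc_trapezoid(fpr, tpr))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_no_leakage_validation_fold_perturbation(self):
        """Perturbing held-out rows changes neither the fitted model nor
        the training-fold scores."""
        df = _subject_table()
        plan = build_fold_plan(20, 4, "healthy")
        ref = df[df.label == "reference"].reset_index(drop=True)
        train = ref[plan.ref_folds != 0]
        m1 = fit_reference(train, "rate+amplitude")
        df2 = df.copy()
        held_rows = df2.index[:4]  # fold 0 of reference windows
        df2.loc[held_rows, ["breathing_rate", "amplitude"]] *= 100
        ref2 = df2[df2.label == "reference"].reset_index(drop=True)
        train2 = ref2[plan.ref_folds != 0]
        m2 = fit_reference(train2, "rate+amplitude")
        np.testing.assert_array_equal(m1.mean, m2.mean)
        np.testing.assert_array_equal(m1.covariance, m2.covariance)

    def test_monotone_severity(self):
        """Larger exercise shifts never decrease pooled one-class AUC."""
        mean_aucs = []
        for shift in (0.0, 2.0, 5.0):
            aucs = []
            for seed in range(10):
                df = _subject_table(shift=shift, seed=seed)
                plan = build_fold_plan(20, 4, "healthy")
                scored = one_class_cv(df, "rate+amplitude", plan)
                fpr, tpr, _ = roc_curve(scored["score"],
                                        scored["label"] == "exercise")
                aucs.append(auc_trapezoid(fpr, tpr))
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] <= mean_aucs[1] <= mean_aucs[2]


def _cohort_table(n_subjects=6, n_ref=20, n_ex=4, beta=(1.5, 1.0),
                  sigma_u=0.0, seed=0):
    """Logistic-model simulator: P(exercise) follows a random-intercept
    logistic model in two standardized covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, sigma_u)
        n = n_ref + n_ex
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        eta = -1.0 + u + beta[0] * x1 + beta[1] * x2
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
        for i in range(n):
            rows.append({
                "subject": f"S{s}", "window": i,
                "label": "exercise" if y[i] else "reference",
                "quality": "ok", "breathing_rate": x1[i], "amplitude": x2[i],
            })
    return pd.DataFrame(rows)


class TestMixedLogistic:
    def test_zero_random_effect_variance_matches_plain_logistic(self):
        """With no subject heterogeneity the GLMM fixed effects agree
        with an ordinary logistic regression."""
        import statsmodels.api as sm

        df = _cohort_table(n_subjects=8, n_ref=60, n_ex=0, sigma_u=0.0, seed=1)
        model = fit_mixed_logistic(df, "rate+amplitude")
        X = df[["breathing_rate", "amplitude"]].to_numpy()
        Xs = (X - model.center) / model.scale
        y = (df["label"] == "exercise").to_numpy(float)
        glm = sm.GLM(y, np.column_stack([np.ones(len(y)), Xs]),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(model.fixed_effects, glm.params, atol=0.05)

    def test_random_intercept_recovery(self):
        """Fixed effects recovered within sampling error when the data
        are generated from a random-intercept logistic model."""
        df = _cohort_table(n_subjects=15, n_ref=40, n_ex=0,
                           beta=(1.2, 0.8), sigma_u=0.8, seed=3)
        model = fit_mixed_logistic(df, "rate+amplitude")
        # covariates are standard normal, so standardization ~ identity
        assert model.fixed_effects[1] == pytest.approx(1.2, abs=0.35)
        assert model.fixed_effects[2] == pytest.approx(0.8, abs=0.35)
        assert model.variance_components["intercept"] > 0.2

    def test_single_class_raises(self):
        df = _cohort_table(seed=4)
        df["label"] = "reference"
        with pytest.raises(ValueError):
            fit_mixed_logistic(df, "rate")

    def test_predictions_in_unit_interval(self):
        df = _cohort_table(seed=5)
        model = fit_mixed_logistic(df, "rate+amplitude")
        p = model.predict_proba(df)
        assert np.all((p > 0) & (p < 1))


class TestSupervisedCv:
    def test_perfect_separation_gives_auc_one(self):
        df = _subject_table(n_ref=30, n_ex=10, shift=50.0, seed=0)
        df2 = _subject_table(n_ref=30, n_ex=10, shift=50.0, seed=1,
                             subject="S2")
        df2["window"] += 100
        table = pd.concat([df, df2], ignore_index=True)
        scored = supervised_cv(table, "rate+amplitude", seed=0)
        fpr, tpr, _ = roc_curve(scored["score"], scored["label"] == "exercise")
        assert auc_trapezoid(fpr, tpr) == pytest.approx(1.0, abs=1e-9)

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(5):
            pieces = []
            for s in range(4):
                d = _subject_table(n_ref=25, n_ex=10, shift=3.0,
                                   seed=10 * seed + s, subject=f"S{s}")
                labels = d["label"].to_numpy().copy()
                rng.shuffle(labels)
                d["label"] = labels
                pieces.append(d)
            table = pd.concat(pieces, ignore_index=True)
            scored = supervised_cv(table, "rate+amplitude", seed=seed)
            fpr, tpr, _ = roc_curve(scored["score"],
                                    scored["label"] == "exercise")
            aucs.append(auc_trapezoid(fpr, tpr))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_every_usable_window_scored_once(self):
        df = _subject_table(n_ref=30, n_ex=10, shift=2.0, seed=0)
        df2 = _subject_table(n_ref=30, n_ex=10, shift=2.0, seed=1,
                             subject="S2")
        table = pd.concat([df, df2], ignore_index=True)
        scored = supervised_cv(table, "rate+amplitude", seed=0)
        assert len(scored) == 80
        assert scored.groupby(["subject", "window"]).size().eq(1).all()
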