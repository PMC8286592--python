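"""ROC machinery: curve construction, AUC/CI, cut-off selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resppat.evaluate import (
    EvaluateConfig,
    auc_trapezoid,
    auc_with_ci,
    build_comparison,
    comparison_to_markdown,
    delong_auc_variance,
    evaluate_scores,
    roc_curve,
    select_cutoff,
)


def _pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney pair counting with ties worth 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        fpr, tpr, thr = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc_trapezoid(fpr, tpr) == 1.0
        assert any((f == 0 and t == 1) for f, t in zip(fpr, tpr))
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_all_ties_give_diagonal(self):
        fpr, tpr, _ = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert len(fpr) == 2  # single step from (0,0) to (1,1)
        assert auc_trapezoid(fpr, tpr) == 0.5

    def test_monotone_coordinates(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=50)
        y = rng.uniform(size=50) < 0.4
        y[0], y[1] = True, False
        fpr, tpr, _ = roc_curve(s, y)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_auc_equals_pair_counting_oracle(self, seed):
        """Trapezoidal AUC over the tie-grouped ROC equals tie-corrected
        Mann-Whitney pair counting exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        # coarse grid of scores to force ties
        s = rng.integers(0, 6, size=n).astype(float)
        y = rng.uniform(size=n) < 0.5
        y[0], y[1] = True, False
        fpr, tpr, _ = roc_curve(s, y)
        assert auc_trapezoid(fpr, tpr) == pytest.approx(
            _pair_count_auc(s, y), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        s = rng.normal(size=200)
        y = rng.uniform(size=200) < 0.3
        y[:2] = [True, False]
        fpr, tpr, _ = roc_curve(s, y)
        assert auc_trapezoid(fpr, tpr) == pytest.approx(
            roc_auc_score(y, s), abs=1e-12
        )

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40)
        y = rng.uniform(size=40) < 0.5
        y[0], y[1] = True, False
        f1, t1, _ = roc_curve(s, y)
        f2, t2, _ = roc_curve(np.exp(2.0 * s) + 1.0, y)
        assert auc_trapezoid(f1, t1) == pytest.approx(
            auc_trapezoid(f2, t2), abs=1e-12
        )


class TestDeLong:
    def test_variance_matches_structural_oracle(self):
        """DeLong variance on a fixed small example agrees with the
        direct placement-value computation."""
        s = np.array([0.9, 0.7, 0.6, 0.55, 0.4, 0.2])
        y = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        auc, var = delong_auc_variance(s, y)
        pos, neg = s[y], s[~y]
        m, n = len(pos), len(neg)
        # placement values computed by brute force
        v10 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                                 for q in neg]) for p in pos])
        v01 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                                 for p in pos]) for q in neg])
        auc_o = v10.mean()
        var_o = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        assert auc == pytest.approx(auc_o, abs=1e-10)
        assert var == pytest.approx(var_o, abs=1e-10)

    def test_perfect_separation_ci_upper_is_one(self):
        auc, ci = auc_with_ci([3, 4, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_degenerate_class_size_flags_ci(self):
        auc, ci = auc_with_ci([3, 1, 2], [1, 0, 0])
        assert auc == 1.0
        assert np.isnan(ci[0]) and np.isnan(ci[1])

    def test_null_coverage(self):
        """Identically distributed classes: the 95% CI covers 0.5 in at
        least ~90% of runs."""
        rng = np.random.default_rng(42)
        cover = 0
        runs = 100
        for _ in range(runs):
            s = rng.normal(size=80)
            y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
            _, (lo, hi) = auc_with_ci(s, y)
            cover += lo <= 0.5 <= hi
        assert cover / runs >= 0.90

    def test_bootstrap_ci_agrees_roughly_with_delong(self):
        rng = np.random.default_rng(1)
        s = np.r_[rng.normal(1, 1, 60), rng.normal(0, 1, 60)]
        y = np.r_[np.ones(60, bool), np.zeros(60, bool)]
        _, ci_d = auc_with_ci(s, y, EvaluateConfig(ci_method="delong"))
        _, ci_b = auc_with_ci(s, y, EvaluateConfig(ci_method="bootstrap",
                                                   n_bootstrap=500))
        assert ci_d[0] == pytest.approx(ci_b[0], abs=0.06)
        assert ci_d[1] == pytest.approx(ci_b[1], abs=0.06)


class TestCutoff:
    def test_perfect_classifier_corner(self):
        fpr, tpr, thr = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        cutoff, sens, spec = select_cutoff(fpr, tpr, thr)
        assert sens == 1.0 and spec == 1.0

    def test_exact_tie_break_prefers_sensitivity(self):
        # (0, 0.6) and (0.4, 1.0) are equidistant from the corner
        fpr = np.array([0.0, 0.0, 0.4, 1.0])
        tpr = np.array([0.0, 0.6, 1.0, 1.0])
        thr = np.array([np.inf, 0.8, 0.5, 0.1])
        cutoff, sens, spec = select_cutoff(fpr, tpr, thr)
        assert sens == 1.0 and cutoff == 0.5

    def test_diagonal_roc_minimizes_at_midpoint(self):
        fpr = np.array([0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.5, 1.0])
        thr = np.array([np.inf, 0.5, 0.1])
        _, sens, spec = select_cutoff(fpr, tpr, thr)
        assert sens == 0.5 and spec == 0.5

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s = rng.normal(size=30)
            y = rng.uniform(size=30) < 0.5
            y[0], y[1] = True, False
            fpr, tpr, thr = roc_curve(s, y)
            cutoff, sens, spec = select_cutoff(fpr, tpr, thr)
            dist = np.sqrt(fpr**2 + (1 - tpr) ** 2)
            assert np.sqrt((1 - spec) ** 2 + (1 - sens) ** 2) == pytest.approx(
                dist.min(), abs=1e-12
            )

    def test_as_printed_formula_picks_origin(self):
        """The literal printed distance sqrt(FPR^2 + (1+TPR)^2) is
        minimized at the (0, 0) corner, which is why it is treated as a
        typo and only kept for audit."""
        fpr, tpr, thr = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        _, sens, _ = select_cutoff(fpr, tpr, thr, formula="as-printed")
        assert sens == 0.0


class TestEvaluateScores:
    def test_metrics_recomputed_from_raw_scores(self):
        rng = np.random.default_rng(3)
        s = np.r_[rng.normal(2, 1, 40), rng.normal(0, 1, 60)]
        y = np.r_[np.ones(40, bool), np.zeros(60, bool)]
        res = evaluate_scores(s, y)
        pred = s >= res.cutoff
        tp = np.sum(pred & y)
        tn = np.sum(~pred & ~y)
        assert res.accuracy == pytest.approx((tp + tn) / 100)
        assert res.sensitivity == pytest.approx(tp / 40)
        assert res.specificity == pytest.approx(tn / 60)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_cutoff_lies_on_roc(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=50)
        y = rng.uniform(size=50) < 0.5
        y[0], y[1] = True, False
        res = evaluate_scores(s, y)
        on_curve = np.isclose(res.thresholds, res.cutoff).any()
        assert on_curve


class TestComparison:
    def test_single_feature_set_single_row(self):
        rng = np.random.default_rng(5)
        s = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        y = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        res = evaluate_scores(s, y)
        table = build_comparison({"rate": res}, "healthy", "oneclass")
        assert len(table) == 1
        assert table["predictive_variables"].iloc[0] == "Breathing rate"
        assert table[["accuracy", "sensitivity", "specificity", "auc"]].apply(
            lambda c: c.between(0, 1)
        ).all().all()
        md = comparison_to_markdown(table)
        assert "Breathing rate" in md and md.count("|") > 8

    def test_determinism(self):
        rng = np.random.default_rng(6)
        s = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        y = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        t1 = build_comparison({"rate": evaluate_scores(s, y)}, "healthy", "oneclass")
        t2 = build_comparison({"rate": evaluate_scores(s, y)}, "healthy", "oneclass")
        assert t1.equals(t2)
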