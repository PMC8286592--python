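"""ROC analysis and the feature-set comparison panel.

Scores are pooled across subjects (higher = more exercise-like; both the
one-class Mahalanobis distance and the supervised predicted probability
satisfy this).  The panel per feature set reports accuracy, sensitivity
and specificity at the upper-left-corner cut-off — the threshold
minimizing sqrt(FPR^2 + (1-TPR)^2) — together with the AUC and its 95%
confidence interval (DeLong by default, stratified bootstrap as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "EvaluateConfig",
    "RocResult",
    "roc_curve",
    "auc_trapezoid",
    "delong_auc_variance",
    "auc_with_ci",
    "select_cutoff",
    "evaluate_scores",
    "build_comparison",
    "comparison_to_markdown",
]


@dataclass
class EvaluateConfig:
    ci_method: str = "delong"  # or "bootstrap"
    ci_level: float = 0.95
    n_bootstrap: int = 2000
    cutoff_formula: str = "corrected"  # or "as-printed"
    bootstrap_seed: int = 0


@dataclass
class RocResult:
    """ROC panel for one pooled set of scores."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int

    @property
    def roc_points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC over all distinct thresholds.

    A window is called positive (exercise) when score >= threshold.
    Equal scores are grouped into a single step, so ties produce diagonal
    segments; the curve starts at (0, 0) (threshold above the maximum)
    and ends at (1, 1).
    Returns (fpr, tpr, thresholds) with thresholds[0] = +inf.
    """
    s, y = _validate(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(~y)[idx]
    P, N = int(y.sum()), int((~y).sum())
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    thresholds = np.r_[np.inf, s[idx]]
    return fpr, tpr, thresholds


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n - 1 and xs[j + 1] == xs[i]:
            j += 1
        ranks[i:j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance from the structural components.

    The placement values V10 (per positive) and V01 (per negative) give
    var(AUC) = var(V10)/m + var(V01)/n for m positives and n negatives.
    """
    s, y = _validate(scores, labels)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.r_[pos, neg])
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(auc), float(var)


def auc_with_ci(scores, labels, config: EvaluateConfig | None = None
                ) -> tuple[float, tuple[float, float]]:
    """AUC with a two-sided confidence interval, truncated to [0, 1].

    With fewer than two observations in either class the AUC is returned
    with a (nan, nan) interval.
    """
    config = config or EvaluateConfig()
    s, y = _validate(scores, labels)
    m, n = int(y.sum()), int((~y).sum())
    fpr, tpr, _ = roc_curve(s, y)
    auc = auc_trapezoid(fpr, tpr)
    if m < 2 or n < 2:
        return auc, (np.nan, np.nan)
    z = norm.ppf(0.5 + config.ci_level / 2.0)
    if config.ci_method == "delong":
        _, var = delong_auc_variance(s, y)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif config.ci_method == "bootstrap":
        rng = np.random.default_rng(config.bootstrap_seed)
        pos_idx, neg_idx = np.where(y)[0], np.where(~y)[0]
        reps = np.empty(config.n_bootstrap)
        for b in range(config.n_bootstrap):
            bi = np.r_[rng.choice(pos_idx, m), rng.choice(neg_idx, n)]
            f, t, _ = roc_curve(s[bi], y[bi])
            reps[b] = auc_trapezoid(f, t)
        alpha = (1.0 - config.ci_level) / 2.0
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return auc, (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def select_cutoff(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray,
                  formula: str = "corrected") -> tuple[float, float, float]:
    """Threshold closest to the upper-left ROC corner.

    ``corrected`` minimizes sqrt(FPR^2 + (1-TPR)^2); ``as-printed``
    evaluates the literal sqrt(FPR^2 + (1+TPR)^2) variant for audit.
    Ties are broken toward higher sensitivity.  Returns
    (cutoff, sensitivity, specificity).
    """
    if len(fpr) == 0:
        raise ValueError("empty ROC")
    if formula == "corrected":
        dist = np.sqrt(fpr**2 + (1.0 - tpr) ** 2)
    elif formula == "as-printed":
        dist = np.sqrt(fpr**2 + (1.0 + tpr) ** 2)
    else:
        raise ValueError("formula must be 'corrected' or 'as-printed'")
    best = np.min(dist)
    cand = np.where(np.isclose(dist, best, rtol=0, atol=1e-12))[0]
    i = cand[np.argmax(tpr[cand])]
    return float(thresholds[i]), float(tpr[i]), float(1.0 - fpr[i])


def evaluate_scores(scores, labels, config: EvaluateConfig | None = None
                    ) -> RocResult:
    """Full ROC panel: curve, AUC with CI, cut-off and confusion metrics.

    Accuracy, sensitivity and specificity are recomputed from the raw
    scores at the selected cut-off (score >= cutoff -> exercise).
    """
    config = config or EvaluateConfig()
    s, y = _validate(scores, labels)
    fpr, tpr, thr = roc_curve(s, y)
    auc, ci = auc_with_ci(s, y, config)
    cutoff, _, _ = select_cutoff(fpr, tpr, thr, config.cutoff_formula)
    pred = s >= cutoff
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    m, n = int(y.sum()), int((~y).sum())
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, auc_ci=ci,
        cutoff=cutoff, accuracy=(tp + tn) / (m + n),
        sensitivity=tp / m, specificity=tn / n,
        n_positive=m, n_negative=n,
    )


FEATURE_SET_LABELS = {
    "rate": "Breathing rate",
    "amplitude": "Signal amplitude",
    "arima": "ARIMA coefficients",
    "rate+amplitude": "Breathing rate and signal amplitude",
    "rate+amplitude+arima": "Breathing rate, signal amplitude and ARIMA coefficients",
    "fourier": "Fourier coefficients (frequencies <=2 Hz)",
}


def build_comparison(results: dict[str, RocResult], cohort: str, mode: str
                     ) -> pd.DataFrame:
    """One table per (cohort, mode): a row per feature set with Accuracy,
    Sensitivity, Specificity and AUC (95% CI)."""
    rows = []
    for fs, r in results.items():
        rows.append({
            "cohort": cohort,
            "mode": mode,
            "feature_set": fs,
            "predictive_variables": FEATURE_SET_LABELS.get(fs, fs),
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "auc": r.auc,
            "auc_ci_low": r.auc_ci[0],
            "auc_ci_high": r.auc_ci[1],
        })
    return pd.DataFrame(rows)


def comparison_to_markdown(table: pd.DataFrame) -> str:
    lines = ["| Predictive variables | Accuracy | Sensitivity | Specificity | AUC |",
             "|---|---|---|---|---|"]
    for _, r in table.iterrows():
        auc = f"{r['auc']:.3f} ({r['auc_ci_low']:.3f}-{r['auc_ci_high']:.3f})"
        lines.append(
            f"| {r['predictive_variables']} | {r['accuracy']:.3f} | "
            f"{r['sensitivity']:.3f} | {r['specificity']:.3f} | {auc} |"
        )
    return "\n".join(lines)


def plot_roc(results: dict[str, RocResult], path, title: str = "") -> None:
    """Optional ROC figure (one curve per feature set)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for fs, r in results.items():
        ax.plot(r.fpr, r.tpr, label=f"{fs} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
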