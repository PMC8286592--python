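"""Rest-vs-exercise classifiers: per-subject novelty detection and a
supervised mixed-effects logistic model.

One-class route
    Each subject's reference (rest) windows define a multivariate normal
    "normality" model (mean and shrunk covariance, optionally after a
    5-component PCA for the Fourier set).  New windows are scored by their
    Mahalanobis distance

        d(x) = [(x - mu)' Sigma^{-1} (x - mu)]^{1/2}

    under a 5-fold cross-validation on the reference windows: each fold
    is scored by a model learned on the other four.  Healthy-protocol
    subjects have few exercise windows, which are scored by all five fold
    models (five predictions per exercise point); observational (COPD-
    like) subjects have enough exercise windows to partition them across
    folds (one prediction per point).

Supervised route
    A binomial generalized linear mixed model with logit link, fixed
    effects for the feature set and per-subject random intercepts and
    random slopes (diagonal random-effect covariance), fitted by a
    Laplace/MAP approximation.  Evaluated either in-sample or by 5-fold
    cross-validation stratified within subject so that every subject
    contributes to each training fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .features import PcaProjection, fit_pca, project

__all__ = [
    "FEATURE_SETS",
    "feature_columns",
    "ClassifyConfig",
    "ReferenceModel",
    "ReferenceFitError",
    "shrunk_covariance",
    "fit_reference",
    "mahalanobis_score",
    "FoldPlan",
    "build_fold_plan",
    "one_class_cv",
    "run_one_class",
    "MixedLogisticModel",
    "fit_mixed_logistic",
    "supervised_cv",
    "run_supervised",
]

log = logging.getLogger(__name__)

#: the six feature combinations compared throughout; "fourier" expands to
#: the f_* magnitude columns and is PCA-reduced to 5 components.
FEATURE_SETS = {
    "rate": ["breathing_rate"],
    "amplitude": ["amplitude"],
    "arima": ["arima_mu", "arima_phi", "arima_theta"],
    "rate+amplitude": ["breathing_rate", "amplitude"],
    "rate+amplitude+arima": [
        "breathing_rate", "amplitude", "arima_mu", "arima_phi", "arima_theta",
    ],
    "fourier": None,  # resolved to f_* columns at call time
}


def feature_columns(feature_set: str, table: pd.DataFrame) -> list[str]:
    if feature_set not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {feature_set!r}")
    cols = FEATURE_SETS[feature_set]
    if cols is None:
        cols = [c for c in table.columns if c.startswith("f_")]
        if not cols:
            raise ValueError("feature table has no Fourier columns")
    return cols


@dataclass
class ClassifyConfig:
    n_folds: int = 5
    n_pca_components: int = 5
    shrinkage: float | None = None  # None -> data-driven intensity
    min_shrinkage: float = 1e-3
    min_reference_windows: int = 10
    fold_scheme: str = "contiguous"  # or "random"
    vcp_prior_sd: float = 3.0  # prior sd of log random-effect sds (MAP fit)


class ReferenceFitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# covariance shrinkage and the Mahalanobis model
# ---------------------------------------------------------------------------

def shrunk_covariance(X: np.ndarray, shrinkage: float | None = None,
                      min_shrinkage: float = 1e-3) -> tuple[np.ndarray, float]:
    """Sample covariance shrunk toward its own diagonal.

    The data-driven intensity is the Schaefer-Strimmer estimate
    lambda* = sum_{i!=j} Var(s_ij) / sum_{i!=j} s_ij^2 (clipped to
    [min_shrinkage, 1]), which keeps the matrix positive-definite even
    when the raw covariance is singular (e.g. duplicated features) while
    leaving well-conditioned covariances nearly untouched.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    target = np.diag(np.diag(S))
    if shrinkage is None:
        if p == 1:
            lam = min_shrinkage
        else:
            W = Xc[:, :, None] * Xc[:, None, :]  # (n, p, p) products
            wbar = W.mean(axis=0)
            var_s = n / (n - 1) ** 3 * ((W - wbar) ** 2).sum(axis=0)
            off = ~np.eye(p, dtype=bool)
            denom = float((S[off] ** 2).sum())
            lam = float(var_s[off].sum() / denom) if denom > 0 else 1.0
            lam = float(np.clip(lam, min_shrinkage, 1.0))
    else:
        lam = float(np.clip(shrinkage, 0.0, 1.0))
    sigma = (1.0 - lam) * S + lam * target
    # guard against zero-variance features
    jitter = 1e-12 * max(1.0, float(np.trace(sigma)) / p)
    sigma[np.diag_indices_from(sigma)] += jitter
    return sigma, lam


@dataclass
class ReferenceModel:
    """Per-subject normality model for Mahalanobis scoring."""

    mean: np.ndarray
    covariance: np.ndarray
    shrinkage: float
    feature_names: list[str]
    subject_id: str = ""
    pca: PcaProjection | None = None
    _chol: tuple = field(default=None, repr=False)

    def __post_init__(self):
        if self._chol is None:
            self._chol = cho_factor(self.covariance, lower=True)


def fit_reference(rows: pd.DataFrame, feature_set: str,
                  config: ClassifyConfig | None = None,
                  subject_id: str = "", fold: int | None = None
                  ) -> ReferenceModel:
    """Learn mean and shrunk covariance from reference-window rows.

    For the Fourier set a PCA is fitted on the same training rows and the
    covariance is estimated in the reduced space.
    """
    config = config or ClassifyConfig()
    cols = feature_columns(feature_set, rows)
    X = rows[cols].dropna().to_numpy(dtype=float)
    pca = None
    if feature_set == "fourier":
        if X.shape[0] < config.n_pca_components + 1:
            raise ReferenceFitError(
                f"subject {subject_id} fold {fold}: {X.shape[0]} rows "
                f"insufficient for {config.n_pca_components}-component PCA"
            )
        pca = fit_pca(X, config.n_pca_components)
        X = project(pca, X)
    dim = X.shape[1]
    if X.shape[0] < dim + 2:
        raise ReferenceFitError(
            f"subject {subject_id} fold {fold}: {X.shape[0]} rows "
            f"< dim + 2 = {dim + 2}"
        )
    sigma, lam = shrunk_covariance(X, config.shrinkage, config.min_shrinkage)
    return ReferenceModel(
        mean=X.mean(axis=0), covariance=sigma, shrinkage=lam,
        feature_names=cols, subject_id=subject_id, pca=pca,
    )


def mahalanobis_score(model: ReferenceModel, x: np.ndarray) -> float | np.ndarray:
    """Mahalanobis distance of one vector (or a matrix of rows) from the
    reference model, via a Cholesky solve (no explicit inverse).

    Rows containing missing values score NaN.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if model.pca is not None:
        out = np.full(X.shape[0], np.nan)
        good = np.all(np.isfinite(X), axis=1)
        if good.any():
            Z = project(model.pca, X[good])
            out[good] = _maha(model, Z)
    else:
        out = np.full(X.shape[0], np.nan)
        good = np.all(np.isfinite(X), axis=1)
        if good.any():
            out[good] = _maha(model, X[good])
    return float(out[0]) if np.ndim(x) == 1 else out


def _maha(model: ReferenceModel, Z: np.ndarray) -> np.ndarray:
    D = Z - model.mean
    sol = cho_solve(model._chol, D.T)
    return np.sqrt(np.maximum(np.einsum("ij,ji->i", D, sol), 0.0))


# ---------------------------------------------------------------------------
# one-class cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Per-subject assignment of usable windows to folds.

    ``ref_folds`` maps each reference-row position to a fold id.
    ``ex_folds`` is None for the healthy scheme (every exercise window is
    scored in all folds) or a fold id per exercise row for the COPD
    scheme (one prediction per point).
    """

    ref_folds: np.ndarray
    ex_folds: np.ndarray | None
    n_folds: int
    seed: int = 0


def _split_contiguous(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return np.repeat(np.arange(k), sizes)


def build_fold_plan(n_reference: int, n_exercise: int, cohort: str,
                    config: ClassifyConfig | None = None, seed: int = 0
                    ) -> FoldPlan:
    """Fold assignment for one subject.

    Contiguous blocks by default (respecting the temporal ordering of the
    windows); ``fold_scheme="random"`` shuffles assignments with the
    given seed.
    """
    config = config or ClassifyConfig()
    k = config.n_folds
    ref = _split_contiguous(n_reference, k)
    ex = _split_contiguous(n_exercise, k) if cohort == "copd" else None
    if config.fold_scheme == "random":
        rng = np.random.default_rng(seed)
        ref = ref[rng.permutation(n_reference)]
        if ex is not None:
            ex = ex[rng.permutation(n_exercise)]
    return FoldPlan(ref_folds=ref, ex_folds=ex, n_folds=k, seed=seed)


def one_class_cv(sub_df: pd.DataFrame, feature_set: str, plan: FoldPlan,
                 config: ClassifyConfig | None = None) -> pd.DataFrame:
    """Cross-validated Mahalanobis scores for one subject.

    ``sub_df`` holds this subject's usable (quality-ok, complete-feature)
    windows.  Per fold, the reference model (and, for the Fourier set,
    its PCA) is fitted on the other four reference folds; the held-out
    reference fold and the planned exercise windows are scored.
    """
    config = config or ClassifyConfig()
    cols = feature_columns(feature_set, sub_df)
    ref = sub_df[sub_df["label"] == "reference"].reset_index(drop=True)
    ex = sub_df[sub_df["label"] == "exercise"].reset_index(drop=True)
    if len(ref) < config.min_reference_windows:
        raise ReferenceFitError(
            f"subject {sub_df['subject'].iloc[0]}: only {len(ref)} usable "
            f"reference windows (< {config.min_reference_windows})"
        )
    out = []
    for f in range(plan.n_folds):
        train = ref[plan.ref_folds != f]
        model = fit_reference(train, feature_set, config,
                              subject_id=str(ref["subject"].iloc[0]), fold=f)
        held = ref[plan.ref_folds == f]
        if plan.ex_folds is None:
            ex_rows = ex
        else:
            ex_rows = ex[plan.ex_folds == f]
        for rows in (held, ex_rows):
            if len(rows) == 0:
                continue
            scores = mahalanobis_score(model, rows[cols].to_numpy(dtype=float))
            for (_, r), s in zip(rows.iterrows(), np.atleast_1d(scores)):
                out.append({
                    "subject": r["subject"], "window": r["window"],
                    "fold": f, "feature_set": feature_set,
                    "score": s, "label": r["label"],
                })
    return pd.DataFrame(out)


def _usable(table: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    cols = feature_columns(feature_set, table)
    mask = (
        (table["quality"] == "ok")
        & table["label"].isin(["reference", "exercise"])
        & table[cols].notna().all(axis=1)
    )
    return table[mask]


def run_one_class(table: pd.DataFrame, feature_set: str, cohort: str,
                  config: ClassifyConfig | None = None, seed: int = 0
                  ) -> pd.DataFrame:
    """Pool one-class CV scores over all subjects of a feature table.

    Subjects with too few usable reference windows are skipped with a
    logged warning.
    """
    config = config or ClassifyConfig()
    usable = _usable(table, feature_set)
    pieces = []
    for i, (sid, sub) in enumerate(usable.groupby("subject", sort=True)):
        sub = sub.sort_values("window")
        n_ref = int((sub["label"] == "reference").sum())
        n_ex = int((sub["label"] == "exercise").sum())
        plan = build_fold_plan(n_ref, n_ex, cohort, config, seed=seed + i)
        try:
            pieces.append(one_class_cv(sub, feature_set, plan, config))
        except ReferenceFitError as err:
            log.warning("skipping subject %s (%s): %s", sid, feature_set, err)
    if not pieces:
        return pd.DataFrame(
            columns=["subject", "window", "fold", "feature_set", "score", "label"]
        )
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# supervised mixed-effects logistic model
# ---------------------------------------------------------------------------

@dataclass
class MixedLogisticModel:
    """Fitted binomial GLMM: logit link, per-subject random intercepts and
    slopes with diagonal random-effect covariance."""

    fixed_effects: np.ndarray  # intercept + standardized covariates
    random_effects: dict[str, np.ndarray]  # term -> per-subject deviations
    variance_components: dict[str, float]  # term -> random-effect sd
    subjects: list[str]
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    converged: bool = True
    fallback: str | None = None

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """P(exercise) for rows of known subjects (unknown subjects get
        random effects of zero)."""
        X = (df[self.feature_names].to_numpy(dtype=float) - self.center) / self.scale
        eta = self.fixed_effects[0] + X @ self.fixed_effects[1:]
        idx = {s: i for i, s in enumerate(self.subjects)}
        rows_sub = df["subject"].map(idx).to_numpy()
        known = pd.notna(rows_sub)
        sub_i = np.where(known, rows_sub, 0).astype(int)
        u0 = self.random_effects["intercept"]
        eta = eta + np.where(known, u0[sub_i], 0.0)
        for j, name in enumerate(self.feature_names):
            uj = self.random_effects[name]
            eta = eta + np.where(known, uj[sub_i], 0.0) * X[:, j]
        return 1.0 / (1.0 + np.exp(-eta))


def _standardize(train: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = train[cols].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale < 1e-12] = 1.0
    return center, scale


def fit_mixed_logistic(table: pd.DataFrame, feature_set: str,
                       config: ClassifyConfig | None = None,
                       feature_cols: list[str] | None = None
                       ) -> MixedLogisticModel:
    """Fit the binomial GLMM by Laplace/MAP approximation.

    Covariates are standardized on the training data.  On failure of the
    full random-intercept-and-slope fit, falls back to random intercepts
    only, then to a plain logistic regression (logged).
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    config = config or ClassifyConfig()
    cols = feature_cols if feature_cols is not None else feature_columns(feature_set, table)
    df = table.dropna(subset=cols).copy()
    y = (df["label"] == "exercise").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the classifier")
    subjects = sorted(df["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    center, scale = _standardize(df, cols)
    X = (df[cols].to_numpy(dtype=float) - center) / scale
    n, p = X.shape
    exog = np.column_stack([np.ones(n), X])

    sub_idx = df["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    n_sub = len(subjects)
    dummies = np.zeros((n, n_sub))
    dummies[np.arange(n), sub_idx] = 1.0
    vc_blocks = [dummies] + [dummies * X[:, j:j + 1] for j in range(p)]
    exog_vc = np.column_stack(vc_blocks)
    ident = np.repeat(np.arange(p + 1), n_sub)
    term_names = ["intercept"] + cols

    def _unpack(res, n_terms):
        fe = np.asarray(res.fe_mean)
        vc = np.asarray(res.vc_mean)
        vcp = np.exp(np.asarray(res.vcp_mean))
        rand = {term_names[t]: vc[ident == t] for t in range(n_terms)}
        sds = {term_names[t]: float(vcp[t]) for t in range(n_terms)}
        return fe, rand, sds

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = BinomialBayesMixedGLM(y, exog, exog_vc, ident,
                                      vcp_p=config.vcp_prior_sd)
            res = m.fit_map()
        fe, rand, sds = _unpack(res, p + 1)
        return MixedLogisticModel(fe, rand, sds, subjects, cols, center, scale)
    except Exception as err:  # pragma: no cover - fallback path
        log.warning("full GLMM failed (%s); retrying random intercepts only", err)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = BinomialBayesMixedGLM(y, exog, dummies,
                                      np.zeros(n_sub, dtype=int),
                                      vcp_p=config.vcp_prior_sd)
            res = m.fit_map()
        fe = np.asarray(res.fe_mean)
        rand = {"intercept": np.asarray(res.vc_mean)}
        rand.update({c: np.zeros(n_sub) for c in cols})
        sds = {"intercept": float(np.exp(res.vcp_mean[0]))}
        sds.update({c: 0.0 for c in cols})
        return MixedLogisticModel(fe, rand, sds, subjects, cols, center, scale,
                                  fallback="random_intercept_only")
    except Exception as err:  # pragma: no cover
        log.warning("random-intercept GLMM failed (%s); plain logistic", err)
        import statsmodels.api as sm
        res = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        fe = np.asarray(res.params)
        rand = {"intercept": np.zeros(n_sub)}
        rand.update({c: np.zeros(n_sub) for c in cols})
        sds = {t: 0.0 for t in term_names}
        return MixedLogisticModel(fe, rand, sds, subjects, cols, center, scale,
                                  fallback="plain_logistic")


def _stratified_subject_folds(df: pd.DataFrame, n_folds: int, seed: int
                              ) -> np.ndarray:
    """Fold id per row: within each subject, reference and exercise
    windows are split separately into contiguous blocks so every subject
    (and, where possible, both classes) appears in each training fold.
    A per-subject rotation offsets which fold gets the extra windows."""
    folds = np.zeros(len(df), dtype=int)
    for k, (_, sub) in enumerate(df.groupby("subject", sort=True)):
        for lab in ("reference", "exercise"):
            pos = sub.index[sub["label"] == lab]
            assign = (_split_contiguous(len(pos), n_folds) + k) % n_folds
            folds[df.index.get_indexer(pos)] = assign
    return folds


def supervised_cv(table: pd.DataFrame, feature_set: str,
                  config: ClassifyConfig | None = None, seed: int = 0,
                  eval_mode: str = "cv") -> pd.DataFrame:
    """Predicted exercise probabilities per window under the GLMM.

    ``eval_mode="cv"`` (default): 5-fold within-subject-stratified
    cross-validation; for the Fourier set the 5-component PCA is refitted
    on each training fold before the GLMM sees the data.
    ``eval_mode="in-sample"``: single fit on all rows.
    """
    config = config or ClassifyConfig()
    cols = feature_columns(feature_set, table)
    usable = _usable(table, feature_set).sort_values(["subject", "window"])
    usable = usable.reset_index(drop=True)
    if usable.empty:
        raise ValueError("no usable windows for feature set " + feature_set)

    def _prepare(train, test):
        """Reduce Fourier rows through a training-fold PCA."""
        if feature_set != "fourier":
            return train, test, cols
        pca = fit_pca(train[cols].to_numpy(dtype=float), config.n_pca_components)
        pc_cols = [f"pc{i + 1}" for i in range(config.n_pca_components)]
        tr = train[["subject", "window", "label"]].copy()
        tr[pc_cols] = project(pca, train[cols].to_numpy(dtype=float))
        te = test[["subject", "window", "label"]].copy()
        te[pc_cols] = project(pca, test[cols].to_numpy(dtype=float))
        return tr, te, pc_cols

    out = []
    if eval_mode == "in-sample":
        tr, te, use_cols = _prepare(usable, usable)
        model = fit_mixed_logistic(tr, feature_set, config, feature_cols=use_cols)
        probs = model.predict_proba(te)
        fold_ids = np.full(len(usable), -1)
        _collect(out, usable, probs, fold_ids, feature_set)
    elif eval_mode == "cv":
        folds = _stratified_subject_folds(usable, config.n_folds, seed)
        for f in range(config.n_folds):
            train, test = usable[folds != f], usable[folds == f]
            if test.empty or train["label"].nunique() < 2:
                continue
            tr, te, use_cols = _prepare(train, test)
            model = fit_mixed_logistic(tr, feature_set, config, feature_cols=use_cols)
            probs = model.predict_proba(te)
            _collect(out, test, probs, np.full(len(test), f), feature_set)
    else:
        raise ValueError("eval_mode must be 'cv' or 'in-sample'")
    return pd.DataFrame(out)


def _collect(out: list, rows: pd.DataFrame, probs: np.ndarray,
             fold_ids: np.ndarray, feature_set: str) -> None:
    for (_, r), pr, f in zip(rows.iterrows(), probs, fold_ids):
        out.append({
            "subject": r["subject"], "window": r["window"], "fold": int(f),
            "feature_set": feature_set, "score": float(pr), "label": r["label"],
        })


def run_supervised(table: pd.DataFrame, feature_set: str,
                   config: ClassifyConfig | None = None, seed: int = 0,
                   eval_mode: str = "cv") -> pd.DataFrame:
    """Alias of :func:`supervised_cv` for symmetry with the one-class API."""
    return supervised_cv(table, feature_set, config, seed, eval_mode)
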