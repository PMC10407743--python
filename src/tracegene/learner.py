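"""The two-layer stacked tissue-risk classifier.

Layer one: five base learners — XGBoost (150 trees, depth 9, eta 0.1),
random forest (1,000 trees), logistic regression (lbfgs, 100k iterations),
gradient boosting initiated from a fitted logistic model (80 trees), and a
two-hidden-layer MLP. An L1-regularized linear SVM (C = 0.1) selects
features per training set for XGB, LR and LR+GB; RF and the MLP see all
features. The positive:negative class-weight ratio is 0.01 for LR, XGB, RF
and the LR part of LR+GB. Layer two: a meta-MLP over the five base scores
(each min-max scaled to [0, 10]), producing the final 0-10 risk score.

Evaluation uses stratified 10-fold cross-validation with strictly
out-of-fold scores at both layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

#: positive:negative class-weight ratio for the four weighted learners
CLASS_WEIGHT_RATIO = 0.01
#: L1-SVM regularization for prediction-mode feature selection
SELECTION_C_PREDICT = 0.1
#: L1-SVM regularization and feature cap for interpretability models
SELECTION_C_INTERPRET = 2.0
SELECTION_CAP_INTERPRET = 50
N_FOLDS = 10

BASE_LEARNER_NAMES = ("xgb", "rf", "lr", "lr_gb", "mlp")
#: learners whose training is preceded by L1-SVM feature selection
SELECTED_LEARNERS = ("xgb", "lr", "lr_gb")


def scale_scores(raw: np.ndarray) -> np.ndarray:
    """Min-max map of a score vector onto [0, 10]; a constant vector maps to 5."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 5.0)
    return np.clip(10.0 * (raw - lo) / (hi - lo), 0.0, 10.0)


class L1SvmSelector(SelectorMixin, BaseEstimator):
    """Feature selection by an L1-regularized linear SVM.

    Keeps features with nonzero coefficients; when ``cap`` is given and
    exceeded, keeps the ``cap`` largest-|coefficient| features (ties broken
    by feature order). Falls back to all features if the penalty zeroes every
    coefficient.
    """

    def __init__(self, C: float = SELECTION_C_PREDICT, cap: int | None = None,
                 max_iter: int = 10000, seed: int = 0) -> None:
        self.C = C
        self.cap = cap
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature selection needs both classes present")
        svm = LinearSVC(
            penalty="l1",
            dual=False,
            C=self.C,
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            svm.fit(X, y)
        coef = np.abs(svm.coef_[0])
        support = coef > 0
        if not support.any():
            support = np.ones_like(support, dtype=bool)
        if self.cap is not None and support.sum() > self.cap:
            idx = np.lexsort((np.arange(coef.size), -coef))[: self.cap]
            support = np.zeros_like(support)
            support[idx] = True
        self.support_ = support
        self.coef_ = svm.coef_[0]
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def make_base_learners(seed: int = 0) -> dict[str, BaseEstimator]:
    """The five configured base learners (fresh, unfitted instances)."""
    cw = {0: 1.0, 1: CLASS_WEIGHT_RATIO}
    return {
        "xgb": XGBClassifier(
            n_estimators=150,
            max_depth=9,
            gamma=0,
            learning_rate=0.1,
            scale_pos_weight=CLASS_WEIGHT_RATIO,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
        ),
        "rf": RandomForestClassifier(
            n_estimators=1000, class_weight=cw, n_jobs=1, random_state=seed
        ),
        "lr": LogisticRegression(
            solver="lbfgs", max_iter=100_000, class_weight=cw, random_state=seed
        ),
        "lr_gb": GradientBoostingClassifier(
            n_estimators=80,
            init=LogisticRegression(
                solver="lbfgs", max_iter=100_000, class_weight=cw, random_state=seed
            ),
            random_state=seed,
        ),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(10, 10),
            activation="relu",
            alpha=0.5,
            batch_size=200,
            random_state=seed,
        ),
    }


def make_meta_learner(seed: int = 0) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(10, 10),
        activation="relu",
        alpha=0.1,
        learning_rate="adaptive",
        learning_rate_init=0.01,
        batch_size=200,
        random_state=seed,
    )


def _fit_quiet(model, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model.fit(X, y)
    return model


def fit_base_learners(
    X: np.ndarray, y: np.ndarray, seed: int = 0, selector_C: float = SELECTION_C_PREDICT
) -> tuple[dict[str, BaseEstimator], L1SvmSelector]:
    """Fit the five base learners on one training set.

    The L1-SVM selector is fitted on the same training rows and applied to
    XGB, LR and LR+GB only.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    selector = L1SvmSelector(C=selector_C, seed=seed).fit(X, y)
    Xs = selector.transform(X)
    learners = make_base_learners(seed)
    for name, model in learners.items():
        _fit_quiet(model, Xs if name in SELECTED_LEARNERS else X, y)
    return learners, selector


def predict_base(
    learners: dict[str, BaseEstimator], selector: L1SvmSelector, X: np.ndarray
) -> np.ndarray:
    """Probability of the positive class per learner; columns follow
    ``BASE_LEARNER_NAMES``."""
    Xs = selector.transform(X)
    cols = []
    for name in BASE_LEARNER_NAMES:
        model = learners[name]
        p = model.predict_proba(Xs if name in SELECTED_LEARNERS else X)[:, 1]
        cols.append(p)
    return np.stack(cols, axis=1)


@dataclass
class TraceScores:
    """Out-of-fold cross-validation output for one tissue."""

    genes: pd.Index
    base_probs: pd.DataFrame  # raw out-of-fold probabilities per learner
    base_scores: pd.DataFrame  # the same scaled to [0, 10] per learner
    meta_probs: pd.Series  # out-of-fold meta probabilities
    trace_scores: pd.Series  # final scores scaled to [0, 10]
    fold_of: pd.Series  # gene -> fold id
    selected_features: dict[int, list[str]]
    metrics: dict = field(default_factory=dict)


def trace_cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    n_folds: int = N_FOLDS,
    selector_C: float = SELECTION_C_PREDICT,
) -> TraceScores:
    """Stratified k-fold evaluation of the full two-layer stack.

    Base learners score each fold with models trained on the other folds;
    the meta-MLP for a fold is likewise trained only on the other folds'
    out-of-fold base scores, so every gene's final score comes from models
    that never saw it.
    """
    genes = X.index
    Xv = X.values
    yv = y.loc[genes].values.astype(int)
    n_pos = int(yv.sum())
    if n_pos < n_folds:
        raise ValueError(
            f"only {n_pos} positives; need >= {n_folds} (or use fewer folds)"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xv, yv))
    oof = np.full((len(genes), len(BASE_LEARNER_NAMES)), np.nan)
    fold_of = np.full(len(genes), -1)
    selected: dict[int, list[str]] = {}
    for k, (tr, te) in enumerate(folds):
        learners, selector = fit_base_learners(
            Xv[tr], yv[tr], seed=seed + k, selector_C=selector_C
        )
        selected[k] = list(X.columns[selector.get_support()])
        oof[te] = predict_base(learners, selector, Xv[te])
        fold_of[te] = k

    base_scores = np.stack([scale_scores(oof[:, j]) for j in range(oof.shape[1])], axis=1)

    meta_oof = np.full(len(genes), np.nan)
    for k, (tr, te) in enumerate(folds):
        meta = make_meta_learner(seed + k)
        _fit_quiet(meta, base_scores[tr], yv[tr])
        meta_oof[te] = meta.predict_proba(base_scores[te])[:, 1]
    trace = scale_scores(meta_oof)

    metrics: dict = {"per_learner": {}, "folds": n_folds, "n_positive": n_pos}
    for j, name in enumerate(BASE_LEARNER_NAMES):
        metrics["per_learner"][name] = _fold_metrics(oof[:, j], yv, fold_of, n_folds)
    metrics["meta"] = _fold_metrics(meta_oof, yv, fold_of, n_folds)
    pred_pos = meta_oof >= 0.5
    neg, pos = yv == 0, yv == 1
    metrics["fpr_at_0.5"] = float(pred_pos[neg].mean()) if neg.any() else float("nan")
    metrics["fnr_at_0.5"] = float((~pred_pos[pos]).mean()) if pos.any() else float("nan")

    return TraceScores(
        genes=genes,
        base_probs=pd.DataFrame(oof, index=genes, columns=BASE_LEARNER_NAMES),
        base_scores=pd.DataFrame(base_scores, index=genes, columns=BASE_LEARNER_NAMES),
        meta_probs=pd.Series(meta_oof, index=genes, name="meta_prob"),
        trace_scores=pd.Series(trace, index=genes, name="trace_score"),
        fold_of=pd.Series(fold_of, index=genes, name="fold"),
        selected_features=selected,
        metrics=metrics,
    )


def _fold_metrics(probs: np.ndarray, y: np.ndarray, fold_of: np.ndarray, n_folds: int) -> dict:
    aucs, aps = [], []
    for k in range(n_folds):
        m = fold_of == k
        if len(np.unique(y[m])) == 2:
            aucs.append(roc_auc_score(y[m], probs[m]))
            aps.append(average_precision_score(y[m], probs[m]))
    return {
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "auprc_mean": float(np.mean(aps)),
        "auprc_sd": float(np.std(aps, ddof=1)) if len(aps) > 1 else 0.0,
        "auc_pooled": float(roc_auc_score(y, probs)),
        "auprc_pooled": float(average_precision_score(y, probs)),
    }


class TraceClassifier(BaseEstimator, ClassifierMixin):
    """Fit the full two-layer stack on a training set; score new genes.

    ``fit`` runs the stratified out-of-fold protocol on the training rows to
    build the meta-learner's training scores, then refits every base learner
    (and the feature selector) on all training rows. ``predict_scores`` maps
    new genes through the full-data base models, the frozen per-learner
    [0, 10] scalings and the meta-MLP, and returns final scores on the
    training-score scale, clipped to [0, 10].

    This is exactly the protocol used to score a patient's held-out candidate
    genes.
    """

    def __init__(self, n_folds: int = N_FOLDS, selector_C: float = SELECTION_C_PREDICT,
                 seed: int = 0) -> None:
        self.n_folds = n_folds
        self.selector_C = selector_C
        self.seed = seed

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        cv = trace_cross_validate(
            X, y, seed=self.seed, n_folds=self.n_folds, selector_C=self.selector_C
        )
        self.cv_ = cv
        self.base_range_ = {
            name: (float(cv.base_probs[name].min()), float(cv.base_probs[name].max()))
            for name in BASE_LEARNER_NAMES
        }
        self.meta_ = make_meta_learner(self.seed)
        _fit_quiet(self.meta_, cv.base_scores.values, y.values.astype(int))
        meta_train = self.meta_.predict_proba(cv.base_scores.values)[:, 1]
        self.meta_range_ = (float(meta_train.min()), float(meta_train.max()))
        self.learners_, self.selector_ = fit_base_learners(
            X.values, y.values.astype(int), seed=self.seed, selector_C=self.selector_C
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _scale_with_range(self, raw: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
        lo, hi = rng
        if hi == lo:
            return np.full_like(raw, 5.0)
        return np.clip(10.0 * (raw - lo) / (hi - lo), 0.0, 10.0)

    def predict_scores(self, X) -> np.ndarray:
        """Final 0-10 scores for new genes."""
        check_is_fitted(self, "meta_")
        X = np.asarray(X)
        probs = predict_base(self.learners_, self.selector_, X)
        scaled = np.stack(
            [
                self._scale_with_range(probs[:, j], self.base_range_[name])
                for j, name in enumerate(BASE_LEARNER_NAMES)
            ],
            axis=1,
        )
        meta_p = self.meta_.predict_proba(scaled)[:, 1]
        return self._scale_with_range(meta_p, self.meta_range_)

    def predict_proba(self, X):
        s = self.predict_scores(X) / 10.0
        return np.stack([1 - s, s], axis=1)

    def predict(self, X):
        return (self.predict_scores(X) >= 5.0).astype(int)


def evaluate(
    scores: pd.Series, labels: pd.Series, groups: pd.Series | None = None
) -> dict:
    """AUC, auPRC, prevalence baseline, and group score comparisons.

    With ``groups`` given, runs Mann-Whitney tests of tissue-associated
    scores against non-disease and against other-disease gene scores
    (one-sided, tissue-associated greater).
    """
    y = labels.loc[scores.index].values.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    out = {
        "auc": float(roc_auc_score(y, scores.values)),
        "auprc": float(average_precision_score(y, scores.values)),
        "prevalence": float(y.mean()),
    }
    if groups is not None:
        g = groups.loc[scores.index]
        s_t = scores[g == "tissue_associated"]
        for other, tag in [("non_disease", "vs_non_disease"), ("other_disease", "vs_other_disease")]:
            s_o = scores[g == other]
            if len(s_t) and len(s_o):
                stat = stats.mannwhitneyu(s_t, s_o, alternative="greater")
                out[f"mw_p_{tag}"] = float(stat.pvalue)
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals), method="bh")
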