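"""Diagnosis classification and symptom prediction from asymmetry features.

Features that survive the network- and region-level group comparisons feed
(1) an L2-regularized logistic regression separating SZ from HC, and (2) a
ridge regression predicting PANSS symptom scores, both evaluated by repeated
nested cross-validation: 100 random 4:1 train/test splits, with the
regularization strength chosen by an inner 5-fold (classification) or 4-fold
(regression) cross-validation on the training set only.  Multi-site features
are ComBat-harmonized within the training and test sets separately (the
split protocol), and standardized by training statistics, so no information
flows from test to train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import (GridSearchCV, KFold, StratifiedKFold,
                                     train_test_split)

from ._utils import MAX_SEED
from .combat import apply_combat, fit_combat
from .exceptions import DataError, SelectionError
from .stats import ComparisonResult

C_GRID = tuple(10.0 ** np.arange(-3, 4))          # inverse reg. strength
ALPHA_GRID = tuple(10.0 ** np.arange(-2, 5))      # ridge reg. strength
N_REPEATS = 100
TEST_FRACTION = 0.2


def select_features(
    network_results: ComparisonResult,
    region_results: ComparisonResult,
) -> list[str]:
    """Union of significant network- and region-level AI features.

    Order-stable: network features first, then region features, each in
    their result-table order.  An empty selection is an error; fall back to
    a fixed a-priori feature set (e.g. all network AIs) if it occurs.
    """
    selected = network_results.significant_features + region_results.significant_features
    if not selected:
        raise SelectionError(
            "no feature passed the significance tests; consider a fallback "
            "set such as all network-level AI features"
        )
    return selected


@dataclass
class PredictionResult:
    """Per-repeat metrics of a repeated nested-CV run."""

    per_repeat: pd.DataFrame
    task: str
    hyperparameter_grid: tuple
    n_repeats: int
    notes: list[str] = field(default_factory=list)

    def summary(self) -> pd.Series:
        metrics = [c for c in self.per_repeat.columns
                   if c not in ("repeat", "hyperparameter")]
        out = {}
        for m in metrics:
            v = self.per_repeat[m].dropna()
            out[f"{m}_mean"] = v.mean()
            out[f"{m}_sd"] = v.std(ddof=1) if len(v) > 1 else 0.0
        return pd.Series(out, name=self.task)


def _repeat_seed(seed: int, repeat: int) -> int:
    return int(np.random.SeedSequence([int(seed) & MAX_SEED, repeat])
               .generate_state(1)[0] % MAX_SEED)


def _split_harmonize(X_tr, X_te, site_tr, site_te, cov_tr, cov_te, notes, repeat):
    """Split-protocol ComBat: fit on train and test separately.

    Falls back to the raw features (with a logged note) when a split leaves
    some site with fewer than two subjects.
    """
    for name, X, s, c in (("train", X_tr, site_tr, cov_tr),
                          ("test", X_te, site_te, cov_te)):
        labels, counts = np.unique(np.asarray(s, dtype=object), return_counts=True)
        if len(labels) < 2 or counts.min() < 2:
            notes.append(f"repeat {repeat}: {name} split leaves a site with <2 "
                         "subjects; harmonization skipped")
            return X_tr, X_te
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_tr = fit_combat(X_tr, site_tr, cov_tr)
        X_tr = apply_combat(m_tr, X_tr, site_tr, cov_tr)
        m_te = fit_combat(X_te, site_te, cov_te)
        X_te = apply_combat(m_te, X_te, site_te, cov_te)
    return X_tr, X_te


def _standardize(X_tr, X_te, notes, repeat):
    """Standardize by training statistics; drop train-constant features."""
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        notes.append(f"repeat {repeat}: dropped {int((~keep).sum())} "
                     "constant feature(s) in training data")
    return ((X_tr[:, keep] - mu[keep]) / sd[keep],
            (X_te[:, keep] - mu[keep]) / sd[keep])


def _prepare(X, y, site, covars):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise DataError("X must be 2-D with one label per row")
    site = None if site is None else np.asarray(site, dtype=object)
    covars = None if covars is None else np.asarray(covars, dtype=float)
    return X, y, site, covars


def classify_nested_cv(
    X,
    y,
    site=None,
    covars=None,
    n_repeats: int = N_REPEATS,
    inner_folds: int = 5,
    c_grid: tuple = C_GRID,
    seed: int = 0,
    return_models: bool = False,
) -> PredictionResult:
    """SZ-vs-HC classification with repeated nested cross-validation.

    Per repeat: stratified 4:1 split, split-protocol harmonization (when
    ``site`` is given), training-statistics standardization, inner
    ``inner_folds``-fold grid search over C (accuracy scoring), refit on the
    full training set, test accuracy and AUC.
    """
    X, y, site, covars = _prepare(X, y, site, covars)
    y = (np.asarray(y, dtype=object) == "SZ").astype(int) if y.dtype == object else y
    if len(np.unique(y)) < 2:
        raise DataError("need both classes present")
    rows, notes, models = [], [], []
    for rep in range(n_repeats):
        rs = _repeat_seed(seed, rep)
        for attempt in range(10):
            idx_tr, idx_te = train_test_split(
                np.arange(len(y)), test_size=TEST_FRACTION,
                stratify=y, random_state=(rs + attempt) % MAX_SEED)
            if len(np.unique(y[idx_tr])) == 2 and len(np.unique(y[idx_te])) == 2:
                if attempt:
                    notes.append(f"repeat {rep}: re-drew split {attempt} time(s)")
                break
        X_tr, X_te = X[idx_tr], X[idx_te]
        if site is not None:
            X_tr, X_te = _split_harmonize(
                X_tr, X_te, site[idx_tr], site[idx_te],
                None if covars is None else covars[idx_tr],
                None if covars is None else covars[idx_te], notes, rep)
        X_tr, X_te = _standardize(X_tr, X_te, notes, rep)
        inner = StratifiedKFold(inner_folds, shuffle=True, random_state=rs)
        # LogisticRegression penalizes with L2 by default (ridge-type)
        search = GridSearchCV(
            LogisticRegression(solver="lbfgs", max_iter=5000),
            {"C": list(c_grid)}, cv=inner, scoring="accuracy")
        search.fit(X_tr, y[idx_tr])
        clf = search.best_estimator_
        prob = clf.predict_proba(X_te)[:, 1]
        rows.append({
            "repeat": rep,
            "accuracy": accuracy_score(y[idx_te], clf.predict(X_te)),
            "auc": roc_auc_score(y[idx_te], prob),
            "hyperparameter": search.best_params_["C"],
        })
        if return_models:
            models.append(clf.coef_.copy())
    result = PredictionResult(pd.DataFrame(rows), "classification",
                              tuple(c_grid), n_repeats, notes)
    if return_models:
        result.models = models
    return result


def regress_nested_cv(
    X,
    y,
    site=None,
    covars=None,
    n_repeats: int = N_REPEATS,
    inner_folds: int = 4,
    alpha_grid: tuple = ALPHA_GRID,
    seed: int = 0,
) -> PredictionResult:
    """PANSS prediction by ridge regression with repeated nested CV.

    Per repeat: plain random 4:1 split, split-protocol harmonization,
    training-statistics standardization, inner ``inner_folds``-fold grid
    search over alpha (MSE scoring), test-set Pearson correlation between
    empirical and predicted scores.  Near-constant targets in a split leave
    r undefined (NaN) and the repeat flagged.
    """
    X, y, site, covars = _prepare(X, np.asarray(y, dtype=float), site, covars)
    if np.any(np.isnan(y)):
        raise DataError("scores must be present for all included subjects")
    rows, notes = [], []
    for rep in range(n_repeats):
        rs = _repeat_seed(seed, rep)
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), test_size=TEST_FRACTION, random_state=rs)
        X_tr, X_te = X[idx_tr], X[idx_te]
        if site is not None:
            X_tr, X_te = _split_harmonize(
                X_tr, X_te, site[idx_tr], site[idx_te],
                None if covars is None else covars[idx_tr],
                None if covars is None else covars[idx_te], notes, rep)
        X_tr, X_te = _standardize(X_tr, X_te, notes, rep)
        inner = KFold(inner_folds, shuffle=True, random_state=rs)
        search = GridSearchCV(Ridge(), {"alpha": list(alpha_grid)}, cv=inner,
                              scoring="neg_mean_squared_error")
        search.fit(X_tr, y[idx_tr])
        pred = search.best_estimator_.predict(X_te)
        if np.std(y[idx_te]) < 1e-12 or np.std(pred) < 1e-12:
            notes.append(f"repeat {rep}: near-constant target or prediction; "
                         "r undefined")
            r = np.nan
        else:
            r = float(sps.pearsonr(y[idx_te], pred)[0])
        rows.append({"repeat": rep, "r": r,
                     "hyperparameter": search.best_params_["alpha"]})
    return PredictionResult(pd.DataFrame(rows), "regression",
                            tuple(alpha_grid), n_repeats, notes)


def auc_by_ranks(y_true, scores) -> float:
    """AUC via the Mann-Whitney rank statistic (cross-check for ROC AUC)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("need both classes for AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
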