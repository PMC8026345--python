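"""Age-group classification from two behavioral features.

Feature 1 is the mean amount of learning across blocks; feature 2 the
change in mean response time from block 4 to block 5, i.e. across the
session midpoint where the approach directions change — older subjects
show a transient slow-down when familiar places are suddenly seen from
novel viewpoints.  An L2-regularized logistic regression is evaluated by
nested stratified cross-validation: the outer folds give held-out AUCs,
an inner fold loop on each training split selects the regularization
strength from a log-spaced grid, and z-scoring parameters are fitted on
training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["ClassifierReport", "rt_change_feature", "classify_age"]

C_GRID = np.logspace(-3, 3, 13)


@dataclass
class ClassifierReport:
    """Nested-CV logistic-regression results.

    ``probability_young`` holds out-of-fold predicted probabilities of
    belonging to the younger group, one per subject; higher values mean
    behavior more typical of younger adults (more learning, no midpoint
    response-time cost).
    """

    probability_young: pd.Series
    fold_auc: np.ndarray
    mean_auc: float
    sd_auc: float
    chosen_C: np.ndarray


def rt_change_feature(trials: pd.DataFrame,
                      pre_block: int = 4, post_block: int = 5) -> float:
    """Mean response time in ``post_block`` minus mean in ``pre_block``.

    Uses observed retrieval trials only.  Returns NaN (missing-feature
    flag) if either block has no observed response time.
    """
    retrieval = trials[(trials["trial_kind"] == "retrieval")
                       & ~trials["missing"].astype(bool)]
    pre = retrieval.loc[retrieval["block"] == pre_block, "response_time"].dropna()
    post = retrieval.loc[retrieval["block"] == post_block, "response_time"].dropna()
    if pre.empty or post.empty:
        return float("nan")
    return float(post.mean() - pre.mean())


def classify_age(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                 folds: int = 10, seed: int = 0) -> ClassifierReport:
    """Nested stratified CV classification of age group.

    ``features`` is a two-column numeric table (one row per subject);
    ``labels`` the age group ('young'/'old').  AUC is computed per outer
    fold from the held-out predicted probabilities and averaged.
    """
    X = np.asarray(features, float)
    y = np.asarray([1 if lab == "young" else 0 for lab in np.asarray(labels)])
    if X.ndim != 2:
        raise ValueError("features must be 2-D (subjects x features)")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 subjects per class")
    keep = X.std(axis=0) > 1e-12
    if not keep.all():
        warnings.warn("dropping constant feature(s)", stacklevel=2)
        X = X[:, keep]

    folds = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    proba = np.full(len(y), np.nan)
    fold_auc, chosen = [], []
    for train, test in outer.split(X, y):
        inner_folds = min(folds, int(y[train].sum()), int((1 - y[train]).sum()))
        model = Pipeline([
            ("scale", StandardScaler()),
            ("logit", LogisticRegressionCV(
                Cs=C_GRID, penalty="l2", solver="liblinear",
                cv=StratifiedKFold(inner_folds, shuffle=True,
                                   random_state=seed % (2**31)),
                scoring="roc_auc", max_iter=5000,
            )),
        ])
        model.fit(X[train], y[train])
        p = model.predict_proba(X[test])[:, list(model.classes_).index(1)]
        proba[test] = p
        if len(np.unique(y[test])) == 2:
            fold_auc.append(roc_auc_score(y[test], p))
        chosen.append(float(model.named_steps["logit"].C_[0]))
    fold_auc = np.asarray(fold_auc)
    index = (features.index if isinstance(features, pd.DataFrame)
             else pd.RangeIndex(len(y)))
    return ClassifierReport(
        probability_young=pd.Series(proba, index=index, name="p_young"),
        fold_auc=fold_auc,
        mean_auc=float(fold_auc.mean()),
        sd_auc=float(fold_auc.std()),
        chosen_C=np.asarray(chosen),
    )
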