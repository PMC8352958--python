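"""Random-forest disease classifier over gene features.

Candidate genes come from the differential-abundance ranking (top 100 by
default).  Model evaluation follows the cross-validated error-curve scheme:
genes are ranked by forest variable importance, added to the model one at a
time, and the misclassification error estimated by 10-fold stratified CV over
five independent trials.  The feature-selection rule takes the minimum of the
trial-averaged error curve plus the between-trial standard deviation at that
point as a cutoff and keeps the smallest gene set whose mean error falls
strictly below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "candidate_genes",
    "cv_error_curve",
    "CvCurve",
    "select_features",
    "train_and_score",
    "roc_auc",
]


def candidate_genes(differential_results: pd.DataFrame, top_n: int = 100) -> list[str]:
    """Top differentially abundant features by (q asc, P asc, |mean-rank gap|
    desc); returns all available when fewer than ``top_n`` exist."""
    df = differential_results.copy()
    df["_gap"] = -(df["mean_rank_case"] - df["mean_rank_control"]).abs()
    ordered = df.sort_values(["q", "p", "_gap"], kind="mergesort")
    return list(ordered.index[:top_n])


@dataclass
class CvCurve:
    ms: np.ndarray  # number of top genes at each curve point
    mean_error: np.ndarray
    sd_error: np.ndarray  # between-trial sd at each point
    per_trial: np.ndarray  # trials x points
    gene_ranking: list[str]  # consensus importance ranking (for reporting)


def _rank_by_importance(X: np.ndarray, y: np.ndarray, rs: int, n_estimators: int) -> np.ndarray:
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=rs, n_jobs=1
    ).fit(X, y)
    # stable ordering under importance ties
    return np.argsort(-forest.feature_importances_, kind="mergesort")


def cv_error_curve(
    profile: pd.DataFrame,
    labels: pd.Series,
    n_trials: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    max_genes: int | None = None,
    importance: str = "fold",
) -> CvCurve:
    """Averaged cross-validation error versus number of top-importance genes.

    Per trial, stratified ``n_folds``-fold CV: within each training fold genes
    are ranked by forest mean-decrease-in-impurity importance (the
    ``importance='global'`` variant ranks once per trial on all data), and a
    forest on the top-m genes is scored on the held-out fold for each m.
    Errors are pooled over folds per trial; the mean and between-trial sd per
    m form the averaged curve.
    """
    y = labels.loc[profile.index].to_numpy()
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if min(np.bincount(y_codes)) < n_folds:
        raise ValueError("each class needs at least n_folds samples")
    X = profile.to_numpy(dtype=float)
    M = X.shape[1] if max_genes is None else min(max_genes, X.shape[1])
    ms = np.arange(1, M + 1)
    per_trial = np.zeros((n_trials, M))
    for t in range(n_trials):
        t_seed = seed + 1000 * t
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=t_seed)
        if importance == "global":
            global_order = _rank_by_importance(X, y_codes, t_seed, n_estimators)
        wrong = np.zeros(M)
        for f, (tr, te) in enumerate(skf.split(X, y_codes)):
            order = (
                global_order
                if importance == "global"
                else _rank_by_importance(X[tr], y_codes[tr], t_seed + f, n_estimators)
            )
            for mi, m in enumerate(ms):
                cols = order[:m]
                clf = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=t_seed + f, n_jobs=1
                ).fit(X[np.ix_(tr, cols)], y_codes[tr])
                pred = clf.predict(X[np.ix_(te, cols)])
                wrong[mi] += (pred != y_codes[te]).sum()
        per_trial[t] = wrong / len(y)
    ranking = _rank_by_importance(X, y_codes, seed, n_estimators)
    return CvCurve(
        ms=ms,
        mean_error=per_trial.mean(axis=0),
        sd_error=per_trial.std(axis=0, ddof=1) if n_trials > 1 else np.zeros(M),
        per_trial=per_trial,
        gene_ranking=[profile.columns[i] for i in ranking],
    )


def select_features(curve: CvCurve, tol: float = 1e-9) -> tuple[int, list[str]]:
    """The min-plus-SD rule on the averaged error curve.

    cutoff = min(mean error) + between-trial sd at the argmin; the selected m
    is the smallest with mean error below the cutoff, and the gene set is the
    top-m of the consensus ranking.  ``tol`` absorbs floating-point noise so
    an error exactly at the cutoff (to machine precision) counts as below it.
    """
    if len(curve.ms) == 0:
        raise ValueError("empty error curve")
    i_min = int(np.argmin(curve.mean_error))
    cutoff = curve.mean_error[i_min] + curve.sd_error[i_min]
    below = np.nonzero(curve.mean_error < cutoff + tol)[0]
    i_sel = int(below[0]) if below.size else i_min
    m = int(curve.ms[i_sel])
    return m, curve.gene_ranking[:m]


def train_and_score(
    profile: pd.DataFrame,
    labels: pd.Series,
    genes: list[str],
    seed: int = 0,
    n_estimators: int = 500,
    case_label: str = "case",
) -> tuple[RandomForestClassifier, pd.Series]:
    """Fit a forest on the selected genes over the full cohort; scores are the
    case-class probabilities on the training samples."""
    missing = [g for g in genes if g not in profile.columns]
    if missing:
        raise KeyError(f"genes absent from profile: {missing}")
    X = profile.loc[:, genes].to_numpy(dtype=float)
    y = (labels.loc[profile.index] == case_label).astype(int).to_numpy()
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    scores = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
    return clf, pd.Series(scores, index=profile.index, name="score")


def score_samples(
    model: RandomForestClassifier, profile: pd.DataFrame, genes: list[str]
) -> pd.Series:
    """Case-probability scores for new samples."""
    X = profile.loc[:, genes].to_numpy(dtype=float)
    return pd.Series(
        model.predict_proba(X)[:, list(model.classes_).index(1)],
        index=profile.index,
        name="score",
    )


def roc_auc(scores, labels, case_label="case") -> tuple[np.ndarray, np.ndarray, float]:
    """ROC staircase and AUC via the rank (Mann-Whitney) formulation."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == case_label or l == 1 else 0 for l in np.asarray(labels)])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    r = rankdata(s)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(auc)
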