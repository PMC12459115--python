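"""Logistic baseline over fixation-prefix vectors and the AUC-vs-m sweep.

Each trial becomes a vector whose first m entries are the ROI codes of its
first m fixations (numeric 1-10 by default), followed by engineered
summary features, followed by the binary group label.  Sweeping
m = 2..20 trades information per trial against data attrition (trials
shorter than m are discarded), so the AUC-vs-m curve is expected to be
inverted-U shaped; its argmax is the optimal prefix length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import Cohort, Group, Trial, filter_min_fixations

__all__ = [
    "ENGINEERED_FEATURES",
    "featurize_trial",
    "build_design_matrix",
    "AUCCurve",
    "auc_vs_m",
    "select_optimal_m",
]

#: Default engineered feature set (dimensions m+1 .. n-1 of the trial
#: vector).  Each is computed on the first m fixations only and can be
#: toggled off by name.
ENGINEERED_FEATURES = ("roi_counts", "mean_duration", "total_duration", "path_length")


def _engineered(trial: Trial, m: int, features: tuple[str, ...]) -> list[float]:
    fixs = trial.fixations[:m]
    vals: list[float] = []
    if "roi_counts" in features:
        codes = np.array([f.roi for f in fixs])
        vals.extend(float((codes == c).sum()) for c in range(1, 11))
    if "mean_duration" in features:
        vals.append(float(np.mean([f.duration for f in fixs])))
    if "total_duration" in features:
        vals.append(float(np.sum([f.duration for f in fixs])))
    if "path_length" in features:
        xy = np.array([(f.x, f.y) for f in fixs])
        vals.append(float(np.sum(np.hypot(*np.diff(xy, axis=0).T))) if m > 1 else 0.0)
    return vals


def featurize_trial(
    trial: Trial,
    m: int,
    features: tuple[str, ...] = ENGINEERED_FEATURES,
    one_hot: bool = False,
) -> np.ndarray:
    """Trial vector: m ROI dims, engineered dims, label last.

    By default ROI codes enter as plain numeric values 1-10; ``one_hot``
    expands each of the m positions into a 10-way indicator instead.
    """
    if len(trial) < m:
        raise ValueError(f"trial has {len(trial)} fixations, fewer than m={m}")
    codes = trial.roi_sequence(m)
    if one_hot:
        block = np.zeros((m, 10))
        block[np.arange(m), codes - 1] = 1.0
        roi_dims = block.ravel()
    else:
        roi_dims = codes.astype(float)
    return np.concatenate([roi_dims, _engineered(trial, m, features), [trial.label]])


def build_design_matrix(
    cohort: Cohort,
    m: int,
    features: tuple[str, ...] = ENGINEERED_FEATURES,
    one_hot: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, subject array) for all trials with >= m fixations."""
    kept = filter_min_fixations(cohort, m)
    vecs = [featurize_trial(t, m, features, one_hot) for t in kept.trials]
    subjects = np.array([t.subject_id for t in kept.trials])
    arr = np.array(vecs)
    if arr.size == 0:
        return np.empty((0, 0)), np.empty(0), subjects
    return arr[:, :-1], arr[:, -1].astype(int), subjects


@dataclass
class AUCCurve:
    """Mean cross-validated AUC and surviving-trial count per m."""

    table: pd.DataFrame  # columns: m, auc, n_trials, flagged

    def valid(self) -> pd.DataFrame:
        return self.table[~self.table["flagged"]]


def _classifier(seed: int):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, random_state=seed),
    )


def _subject_folds(cohort: Cohort) -> list[tuple[set, set]]:
    """Patient-rotation folds (same design as the conv-net CV): one fold
    per patient subject, fold i testing patient i plus a disjoint
    round-robin share of controls, training on everyone else."""
    from .classifier import make_fold_splits

    patients = [
        s for s, g in zip(cohort.subjects["subject"], cohort.subjects["group"])
        if g != Group.CONTROL.value
    ]
    controls = cohort.subject_ids(Group.CONTROL)
    folds = []
    for split in make_fold_splits(patients, controls):
        test = set(split.test_subjects)
        train = set(split.train_subjects) | set(split.val_subjects)
        folds.append((train, test))
    return folds


def auc_vs_m(
    cohort: Cohort,
    m_range: range = range(2, 21),
    seed: int = 0,
    features: tuple[str, ...] = ENGINEERED_FEATURES,
    one_hot: bool = False,
) -> AUCCurve:
    """Cross-validated AUC of the logistic baseline for each m.

    Folds are subject-wise, built by rotating the patient subjects (the
    baseline has no validation stage, so each fold's validation subjects
    join its training set).  An m whose surviving data cannot support the
    CV — a missing class overall or in some fold's train/test split — is
    flagged and its AUC recorded as NaN.
    """
    for m in m_range:
        if not 1 < m <= 20:
            raise ValueError(f"m must satisfy 1 < m <= 20, got {m}")
    folds = _subject_folds(cohort)
    rows = []
    for m in m_range:
        X, y, subjects = build_design_matrix(cohort, m, features, one_hot)
        n_trials = len(y)
        if n_trials == 0 or len(np.unique(y)) < 2:
            rows.append((m, np.nan, n_trials, True))
            continue
        aucs = []
        ok = True
        for train_subs, test_subs in folds:
            tr = np.isin(subjects, list(train_subs))
            te = np.isin(subjects, list(test_subs))
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                ok = False
                break
            clf = _classifier(seed).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
        if ok:
            rows.append((m, float(np.mean(aucs)), n_trials, False))
        else:
            rows.append((m, np.nan, n_trials, True))
    table = pd.DataFrame(rows, columns=["m", "auc", "n_trials", "flagged"])
    return AUCCurve(table)


def select_optimal_m(curve: AUCCurve) -> int:
    """Argmax of mean AUC over valid entries; ties go to the smallest m."""
    valid = curve.valid()
    if len(valid) == 0:
        raise ValueError("AUC curve has no valid entries")
    best = valid["auc"].max()
    return int(valid.loc[np.isclose(valid["auc"], best), "m"].min())
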