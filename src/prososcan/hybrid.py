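"""Non-negative fold-wise combination of the two encoders' predictions.

Per fold, the two conv-net prediction streams are averaged with
non-negative weights chosen to maximize AUC: candidates are the
non-negative least-squares solution plus a convex grid (w, 1-w),
w = 0, 0.05, ..., 1, and the candidate with the highest AUC against the
labels wins.  Non-negativity discards a stream whose predictions
anti-correlate with the labels rather than letting it flip sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.metrics import roc_auc_score

from .core import Cohort, FaceTemplate, filter_min_fixations
from .encoders import render_facial_scanpath, render_roi_sequence

__all__ = ["HybridWeights", "fit_nonnegative_weights", "hybrid_predict", "transfer_classify"]


@dataclass(frozen=True)
class HybridWeights:
    """Selected per-fold weights for (facial scanpath, ROI sequence)."""

    w_facial: float
    w_roiseq: float
    fold: int = -1
    auc: float = np.nan

    def __post_init__(self):
        if self.w_facial < 0 or self.w_roiseq < 0:
            raise ValueError("hybrid weights must be non-negative")
        if self.w_facial == 0 and self.w_roiseq == 0:
            raise ValueError("hybrid weights cannot both be zero")


def fit_nonnegative_weights(
    preds_facial: np.ndarray,
    preds_roiseq: np.ndarray,
    labels: np.ndarray,
    fold: int = -1,
    grid_step: float = 0.05,
) -> HybridWeights:
    """Pick the max-AUC non-negative weighting of two prediction streams.

    Ties are broken toward the most balanced weighting (closest to
    (0.5, 0.5)), then toward the lower facial weight.
    """
    pf = np.asarray(preds_facial, dtype=float)
    pr = np.asarray(preds_roiseq, dtype=float)
    y = np.asarray(labels, dtype=float)
    if pf.shape != pr.shape or pf.shape != y.shape:
        raise ValueError("prediction vectors and labels must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    candidates: list[tuple[float, float]] = []
    coef, _ = nnls(np.column_stack([pf, pr]), y)
    if coef.sum() > 0:
        candidates.append((float(coef[0]), float(coef[1])))
    ws = np.arange(0.0, 1.0 + 1e-9, grid_step)
    candidates += [(float(w), float(1.0 - w)) for w in ws]

    def norm(c):
        # a stream with < 0.1% of the total weight is effectively
        # discarded: snap it to an exact zero so the selected weights say so
        s = c[0] + c[1]
        wf, wr = c[0] / s, c[1] / s
        if wf < 1e-3:
            wf, wr = 0.0, 1.0
        elif wr < 1e-3:
            wf, wr = 1.0, 0.0
        return (wf, wr)

    best = None
    for cand in candidates:
        wf, wr = norm(cand)
        auc = roc_auc_score(y, wf * pf + wr * pr)
        # sort key: max AUC, then min distance from (.5,.5), then min w_facial
        key = (-round(auc, 12), abs(wf - 0.5), wf)
        if best is None or key < best[0]:
            best = (key, (wf, wr), auc)
    (_, (wf, wr), auc) = best
    return HybridWeights(w_facial=wf, w_roiseq=wr, fold=fold, auc=float(auc))


def hybrid_predict(p_facial, p_roiseq, weights: HybridWeights):
    """Weighted average of the two streams, normalized to stay in [0, 1]."""
    total = weights.w_facial + weights.w_roiseq
    return (weights.w_facial * np.asarray(p_facial) + weights.w_roiseq * np.asarray(p_roiseq)) / total


def transfer_classify(
    cohort: Cohort,
    fold_models: list[dict],
    m: int,
    template: FaceTemplate | None = None,
    resolution: int = 128,
    cell_size: int = 8,
    radius_constant: float = 1500.0,
):
    """Apply a trained fold ensemble to an unseen cohort.

    ``fold_models`` holds one dict per trained fold (possibly per
    repetition): keys ``facial`` and ``roiseq`` (ConvNet) and ``weights``
    (HybridWeights).  Every trial with >= m fixations is encoded both
    ways, pushed through every fold's pair of models, combined with that
    fold's hybrid weights, and averaged across folds.

    Returns a DataFrame (subject, group, trial, probability).
    """
    if not fold_models:
        raise ValueError("no trained fold models supplied")
    import pandas as pd

    kept = filter_min_fixations(cohort, m)
    if len(kept) == 0:
        raise ValueError(f"no trials with >= {m} fixations to classify")
    x_f = np.stack(
        [render_facial_scanpath(t, m, radius_constant, resolution, template).pixels
         for t in kept.trials]
    )
    x_r = np.stack([render_roi_sequence(t, m, cell_size).pixels for t in kept.trials])
    fold_probs = []
    for fm in fold_models:
        pf = fm["facial"].predict(x_f)
        pr = fm["roiseq"].predict(x_r)
        fold_probs.append(hybrid_predict(pf, pr, fm["weights"]))
    probs = np.mean(fold_probs, axis=0)
    return pd.DataFrame(
        {
            "subject": [t.subject_id for t in kept.trials],
            "group": [t.group.value for t in kept.trials],
            "trial": [t.trial_id for t in kept.trials],
            "probability": probs,
        }
    )
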