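"""Scan indices, signal-detection scores, permutation significance,
overlay summaries and group statistics.

The three hand-defined scan indices summarize, per subject, the fixation
behavior the image classifiers are expected to exploit:

* ``left:right`` = (L - R) / (L + R) over fixations on the two eyes
  (positive = bias to the eye on the left of the image),
* ``eye:mouth`` = (E - M) / (E + M) with E = fixations on either eye and
  M = fixations on the mouth (positive = eye bias),
* ``dispersion`` = mean over trials of the per-trial standard deviation
  of fixation distances from the face center (px).

All indices use only the first m fixations of trials with at least m
fixations, matching the prefix the classifiers see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Cohort, FaceTemplate, Group, Trial, distance_from_center, filter_min_fixations
from .encoders import DensityMap, Encoder, overlay_density

__all__ = [
    "permutation_test",
    "percentile_overlays",
    "subject_prediction_summary",
    "group_prediction_means",
    "left_right_index",
    "eye_mouth_index",
    "dispersion_index",
    "roi_contrast_profile",
    "DetectionScore",
    "dprime_criterion",
    "one_way_anova",
    "one_tailed_t",
    "pearson_r",
    "contrast_anova",
]


# ---------------------------------------------------------------------------
# permutation significance


def permutation_test(
    runner,
    cohort: Cohort,
    true_auc: float,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Subject-level label-permutation null for a pipeline AUC.

    ``runner(cohort, seed) -> AUC`` re-runs the (possibly reduced)
    pipeline.  Group labels are shuffled across *subjects* (trial counts
    per subject preserved, group sizes preserved), never across trials,
    so the permuted pipeline sees the same subject-wise CV structure as
    the real one.  p = (1 + #{null >= true}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = list(cohort.subjects["subject"])
    groups = [Group(g) for g in cohort.subjects["group"]]
    null_aucs = []
    for i in range(n_perm):
        perm = rng.permutation(len(subjects))
        mapping = {subjects[j]: groups[perm[j]] for j in range(len(subjects))}
        shuffled = cohort.relabeled(mapping)
        null_aucs.append(float(runner(shuffled, int(rng.integers(2**31)))))
    null_aucs = np.array(null_aucs)
    exceed = int(np.sum(null_aucs >= true_auc))
    p = (1 + exceed) / (1 + n_perm)
    return {"p": p, "null_aucs": null_aucs, "true_auc": true_auc, "n_exceed": exceed}


# ---------------------------------------------------------------------------
# overlays and per-subject summaries


def percentile_overlays(
    predictions: pd.DataFrame,
    trials: dict[tuple[str, str], Trial],
    encoder: Encoder,
    m: int,
    lower: float = 10.0,
    upper: float = 90.0,
    **render_kw,
) -> tuple[DensityMap, DensityMap]:
    """Overlay high-confidence trials from each tail of the predictions.

    Percentile thresholds are computed *within each fold*; trials strictly
    below the lower threshold (confident control) and strictly above the
    upper threshold (confident prosopagnosic) are pooled across folds
    regardless of their true group, then overlaid.
    """
    lo_items, hi_items = [], []
    for _, fold_df in predictions.groupby("fold"):
        probs = fold_df["probability"].to_numpy()
        lo_thr = np.percentile(probs, lower)
        hi_thr = np.percentile(probs, upper)
        for _, row in fold_df.iterrows():
            key = (row["subject"], row["trial"])
            if key not in trials:
                continue
            if row["probability"] < lo_thr:
                lo_items.append(trials[key])
            elif row["probability"] > hi_thr:
                hi_items.append(trials[key])
    if not lo_items or not hi_items:
        raise ValueError("empty percentile tail: predictions too concentrated")
    return (
        overlay_density(lo_items, encoder, m, **render_kw),
        overlay_density(hi_items, encoder, m, **render_kw),
    )


def subject_prediction_summary(predictions: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of predicted probability per subject, sorted by
    median; also carries each subject's mean and group for group-level
    summaries of per-subject means."""
    rows = []
    for subject, df in predictions.groupby("subject"):
        p = df["probability"].to_numpy()
        q1, med, q3 = np.percentile(p, [25, 50, 75])
        rows.append(
            {
                "subject": subject,
                "group": df["group"].iloc[0] if "group" in df else None,
                "n_trials": len(p),
                "min": p.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": p.max(),
                "mean": p.mean(),
            }
        )
    return pd.DataFrame(rows).sort_values("median", ignore_index=True)


def group_prediction_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean and SD of the per-subject mean predictions
    (input: the output of :func:`subject_prediction_summary`)."""
    return summary.groupby("group")["mean"].agg(["mean", "std", "count"]).reset_index()


# ---------------------------------------------------------------------------
# scan indices


def _per_subject_ratio_index(
    cohort: Cohort, m: int, pos_rois: tuple[int, ...], neg_rois: tuple[int, ...], name: str
) -> pd.DataFrame:
    kept = filter_min_fixations(cohort, m)
    rows = []
    for sid in kept.subjects["subject"]:
        trials = kept.trials_of(sid)
        if not trials:
            continue
        codes = np.concatenate([t.roi_sequence(m) for t in trials])
        pos = int(np.isin(codes, pos_rois).sum())
        neg = int(np.isin(codes, neg_rois).sum())
        group = next(t.group.value for t in trials)
        if pos + neg == 0:
            rows.append({"subject": sid, "group": group, "index": name,
                         "value": np.nan, "excluded": True})
        else:
            rows.append({"subject": sid, "group": group, "index": name,
                         "value": (pos - neg) / (pos + neg), "excluded": False})
    return pd.DataFrame(rows)


def left_right_index(cohort: Cohort, m: int = 4) -> pd.DataFrame:
    """(L - R)/(L + R) per subject over first-m eye fixations; positive
    means a bias to the eye on the left of the image.  Subjects with no
    eye fixations are flagged excluded (value NaN)."""
    return _per_subject_ratio_index(cohort, m, pos_rois=(1,), neg_rois=(2,), name="left_right")


def eye_mouth_index(cohort: Cohort, m: int = 4) -> pd.DataFrame:
    """(E - M)/(E + M) per subject, E = both eyes, M = mouth; positive
    means an eye bias."""
    return _per_subject_ratio_index(cohort, m, pos_rois=(1, 2), neg_rois=(9,), name="eye_mouth")


def dispersion_index(cohort: Cohort, template: FaceTemplate | None = None, m: int = 16) -> pd.DataFrame:
    """Per subject: mean over eligible trials (>= m fixations) of the
    per-trial sample SD of first-m fixation distances from face center."""
    if template is None:
        template = FaceTemplate.default()
    kept = filter_min_fixations(cohort, m)
    rows = []
    for sid in cohort.subjects["subject"]:
        trials = kept.trials_of(sid)
        group = cohort.subjects.loc[cohort.subjects["subject"] == sid, "group"].iloc[0]
        if not trials:
            rows.append({"subject": sid, "group": group, "index": "dispersion",
                         "value": np.nan, "excluded": True})
            continue
        sds = []
        for t in trials:
            d = [distance_from_center(f, template) for f in t.fixations[:m]]
            sds.append(np.std(d, ddof=1))
        rows.append({"subject": sid, "group": group, "index": "dispersion",
                     "value": float(np.mean(sds)), "excluded": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI contrast profile


def roi_contrast_profile(counts: np.ndarray, label: str = "", repetition: int = 0) -> pd.DataFrame:
    """Per fixation-row contrast of an m x 10 ROI count matrix.

    Contrast = coefficient of variation (population SD / mean) of the 10
    per-ROI counts in that row: 0 when all regions are fixated equally,
    3.0 for a row concentrated on a single region.  Rows whose counts sum
    to zero have undefined contrast and are flagged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 10:
        raise ValueError("counts must be an m x 10 matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    rows = []
    for i, row in enumerate(counts, start=1):
        mean = row.mean()
        if mean == 0:
            rows.append({"fixation": i, "contrast": np.nan, "flagged": True,
                         "group": label, "repetition": repetition})
        else:
            rows.append({"fixation": i, "contrast": float(row.std() / mean), "flagged": False,
                         "group": label, "repetition": repetition})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal detection


@dataclass(frozen=True)
class DetectionScore:
    d_prime: float
    criterion: float
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int


def dprime_criterion(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> DetectionScore:
    """d' = z(H) - z(F), c = -(z(H) + z(F))/2, z the standard-normal
    quantile.  Rates of exactly 0 or 1 are moved in by 1/(2N) before the
    transform (the usual extreme-rate correction)."""
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n_target = hits + misses
    n_distract = false_alarms + correct_rejections
    if n_target == 0 or n_distract == 0:
        raise ValueError("need at least one target and one distractor")

    def rate(k: int, n: int) -> float:
        r = k / n
        if r == 0.0:
            return 1.0 / (2 * n)
        if r == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r

    zh = sps.norm.ppf(rate(hits, n_target))
    zf = sps.norm.ppf(rate(false_alarms, n_distract))
    return DetectionScore(
        d_prime=float(zh - zf),
        criterion=float(-(zh + zf) / 2.0),
        hits=hits,
        misses=misses,
        false_alarms=false_alarms,
        correct_rejections=correct_rejections,
    )


# ---------------------------------------------------------------------------
# group statistics


def one_way_anova(*groups) -> dict:
    """One-way ANOVA across groups of values: F, dfs, p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p)}


def one_tailed_t(a, b, alternative: str = "greater", pooled: bool = True) -> dict:
    """Two-sample t-test of mean(a) vs mean(b), one-tailed, pooled
    variance by default (Welch when ``pooled=False``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=pooled, alternative=alternative)
    df = len(a) + len(b) - 2 if pooled else None
    return {"t": float(t), "df": df, "p": float(p)}


def pearson_r(x, y) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x)}


def contrast_anova(df: pd.DataFrame) -> dict:
    """Two-way repeated-measures ANOVA on contrast profiles.

    Expects columns ``contrast``, ``group`` (between factor: which
    overlay), ``fixation`` (within factor) and ``repetition`` (the
    repeated unit).  Returns F and p for group, fixation and interaction.
    """
    import pingouin as pg

    d = df.rename(columns={"contrast": "dv"}).copy()
    d["unit"] = d["group"].astype(str) + ":" + d["repetition"].astype(str)
    res = pg.mixed_anova(data=d, dv="dv", within="fixation", between="group", subject="unit")
    pcol = "p_unc" if "p_unc" in res.columns else "p-unc"
    out = {}
    for _, row in res.iterrows():
        key = {"group": "group", "fixation": "fixation", "Interaction": "interaction"}.get(
            row["Source"], row["Source"]
        )
        out[key] = {"F": float(row["F"]), "p": float(row[pcol])}
    return out
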