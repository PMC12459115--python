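"""End-to-end two-encoder pipeline: encode, cross-validate, hybridize.

``run_hybrid_pipeline`` wires the stages together for one two-group
cohort: filter trials to >= m fixations, render both encodings, train a
conv-net per fold per encoder (repeated ``n_rep`` times with fresh
initializations), fit per-fold non-negative hybrid weights on the fold's
*validation* predictions, apply them to the fold's test predictions, and
average the per-fold hybrid test AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .classifier import ModelConfig, make_fold_splits, repeat_runs
from .core import Cohort, FaceTemplate, Group, filter_min_fixations
from .encoders import (
    Encoder,
    ScanpathImage,
    render_facial_scanpath,
    render_roi_sequence,
)
from .hybrid import HybridWeights, fit_nonnegative_weights, hybrid_predict

__all__ = ["PipelineConfig", "PipelineResult", "encode_cohort", "run_hybrid_pipeline"]


@dataclass
class PipelineConfig:
    """Rendering + training settings for one pipeline run."""

    m: int = 4
    resolution: int = 128
    cell_size: int = 8
    radius_constant: float = 1500.0
    model: ModelConfig = field(default_factory=ModelConfig)
    n_rep: int = 10

    @classmethod
    def reduced(cls, m: int = 4, n_rep: int = 1, epochs: int = 12) -> "PipelineConfig":
        """Desk-scale settings: 16 px facial raster, 2 px ROI cells, short
        Adam schedule (12 epochs at lr 1e-3).  Used for permutation nulls
        and simulation studies where hundreds of retrainings are needed."""
        return cls(
            m=m,
            resolution=16,
            cell_size=2,
            model=ModelConfig(learning_rate=1e-3, epochs=epochs, patience=4, batch_size=32),
            n_rep=n_rep,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    fold_summaries: pd.DataFrame  # per fold: encoder AUCs, hybrid weights + AUC
    predictions: pd.DataFrame  # per trial/rep/encoder + hybrid test predictions
    hybrid_auc: float  # mean over folds of hybrid test AUC
    encoder_aucs: dict  # encoder value -> mean test AUC over folds
    fold_models: list  # per fold x rep: {"facial", "roiseq", "weights"}

    @property
    def hybrid_test_predictions(self) -> pd.DataFrame:
        return self.predictions[
            (self.predictions["encoder"] == "hybrid") & (self.predictions["split"] == "test")
        ]


def encode_cohort(
    cohort: Cohort,
    m: int,
    encoder: Encoder,
    template: FaceTemplate | None = None,
    resolution: int = 128,
    cell_size: int = 8,
    radius_constant: float = 1500.0,
) -> list[ScanpathImage]:
    """Render every trial with >= m fixations under one encoder."""
    kept = filter_min_fixations(cohort, m)
    if encoder is Encoder.ROI_SEQUENCE:
        return [render_roi_sequence(t, m, cell_size) for t in kept.trials]
    return [
        render_facial_scanpath(t, m, radius_constant, resolution, template)
        for t in kept.trials
    ]


def run_hybrid_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    template: FaceTemplate | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Full cross-validated two-encoder + hybrid analysis of a cohort.

    The cohort must contain exactly one patient group plus controls.
    Folds are built over patient subjects (k = number of patients) with
    controls dealt round-robin across folds.
    """
    config = config or PipelineConfig()
    patient_groups = [g for g in cohort.subjects["group"].unique() if g != Group.CONTROL.value]
    if len(patient_groups) != 1:
        raise ValueError(f"cohort must have exactly one patient group, found {patient_groups}")
    patients = cohort.subject_ids(Group(patient_groups[0]))
    controls = cohort.subject_ids(Group.CONTROL)
    splits = make_fold_splits(patients, controls)

    images = {
        Encoder.FACIAL_SCANPATH: encode_cohort(
            cohort, config.m, Encoder.FACIAL_SCANPATH, template,
            config.resolution, config.cell_size, config.radius_constant),
        Encoder.ROI_SEQUENCE: encode_cohort(
            cohort, config.m, Encoder.ROI_SEQUENCE, template,
            config.resolution, config.cell_size, config.radius_constant),
    }

    group_of = dict(zip(cohort.subjects["subject"], cohort.subjects["group"]))
    fold_rows = []
    all_preds = []
    fold_models = []
    for split in splits:
        runs = {
            enc: repeat_runs(split, imgs, config.model, n_rep=config.n_rep, seed=seed)
            for enc, imgs in images.items()
        }
        rec_f = runs[Encoder.FACIAL_SCANPATH]["records"]
        rec_r = runs[Encoder.ROI_SEQUENCE]["records"]
        hybrid_aucs = []
        for rep in range(config.n_rep):
            f_rep = rec_f[rec_f["repetition"] == rep]
            r_rep = rec_r[rec_r["repetition"] == rep]
            merged = f_rep.merge(
                r_rep,
                on=["fold", "split", "subject", "trial", "label", "repetition"],
                suffixes=("_f", "_r"),
            )
            val = merged[merged["split"] == "val"]
            test = merged[merged["split"] == "test"]
            if val["label"].nunique() == 2:
                weights = fit_nonnegative_weights(
                    val["probability_f"].to_numpy(),
                    val["probability_r"].to_numpy(),
                    val["label"].to_numpy(),
                    fold=split.fold,
                )
            else:  # degenerate validation split: fall back to equal weights
                weights = HybridWeights(0.5, 0.5, fold=split.fold)
            p_hybrid = hybrid_predict(
                test["probability_f"].to_numpy(), test["probability_r"].to_numpy(), weights
            )
            hybrid_aucs.append(
                roc_auc_score(test["label"], p_hybrid) if test["label"].nunique() == 2 else np.nan
            )
            hy = test[["fold", "split", "subject", "trial", "label", "repetition"]].copy()
            hy["encoder"] = "hybrid"
            hy["probability"] = p_hybrid
            all_preds.append(hy)
            fold_models.append(
                {
                    "fold": split.fold,
                    "repetition": rep,
                    "facial": runs[Encoder.FACIAL_SCANPATH]["models"][rep],
                    "roiseq": runs[Encoder.ROI_SEQUENCE]["models"][rep],
                    "weights": weights,
                }
            )
            fold_rows.append(
                {
                    "fold": split.fold,
                    "repetition": rep,
                    "auc_facial": runs[Encoder.FACIAL_SCANPATH]["aucs"][rep],
                    "auc_roiseq": runs[Encoder.ROI_SEQUENCE]["aucs"][rep],
                    "auc_hybrid": hybrid_aucs[-1],
                    "w_facial": weights.w_facial,
                    "w_roiseq": weights.w_roiseq,
                }
            )
        all_preds.append(rec_f)
        all_preds.append(rec_r)

    predictions = pd.concat(all_preds, ignore_index=True)
    predictions["group"] = predictions["subject"].map(group_of)
    summaries = pd.DataFrame(fold_rows)
    per_fold = summaries.groupby("fold").mean(numeric_only=True)
    return PipelineResult(
        config=config,
        fold_summaries=summaries,
        predictions=predictions,
        hybrid_auc=float(np.nanmean(per_fold["auc_hybrid"])),
        encoder_aucs={
            "facial_scanpath": float(np.nanmean(per_fold["auc_facial"])),
            "roi_sequence": float(np.nanmean(per_fold["auc_roiseq"])),
        },
        fold_models=fold_models,
    )


def reduced_auc_runner(config: PipelineConfig | None = None, template: FaceTemplate | None = None):
    """Adapter for :func:`prososcan.stats.permutation_test`: returns a
    callable (cohort, seed) -> hybrid AUC using the given (typically
    reduced) pipeline configuration."""
    cfg = config or PipelineConfig.reduced()

    def _run(cohort: Cohort, seed: int) -> float:
        return run_hybrid_pipeline(cohort, cfg, template, seed=seed).hybrid_auc

    return _run
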