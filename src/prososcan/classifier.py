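"""Subject-wise cross-validation of the conv-net scanpath classifier.

The fold design rotates the patient subjects: with k patients there are k
folds; fold i tests on patient i, validates on the next patient
(cyclically), and trains on the remaining k-2 patients.  Controls are
split into k disjoint subsets that rotate alongside, so no subject's
trials ever appear on both sides of a split.  Each fold is repeated
``n_rep`` times with fresh weight initializations and trial orders; fold
performance is the mean test AUC over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .encoders import ScanpathImage
from .nn import ConvNet, TrainConfig, binary_cross_entropy

__all__ = [
    "ModelConfig",
    "FoldSplit",
    "cross_entropy",
    "make_fold_splits",
    "train_and_predict",
    "repeat_runs",
]


def cross_entropy(y, p) -> float:
    """Mean binary cross-entropy of predictions ``p`` against labels ``y``."""
    return binary_cross_entropy(y, p)


@dataclass
class ModelConfig:
    """Conv-net hyperparameters: 3x3 kernels at stride 2, 3x3 max pools,
    three conv layers of 32/64/128 feature maps, sigmoid output."""

    channels: tuple[int, int, int] = (32, 64, 128)
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10
    class_weight: bool = True

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            patience=self.patience,
            class_weight=self.class_weight,
            seed=seed,
        )


@dataclass(frozen=True)
class FoldSplit:
    """One fold: which subjects are trained on, validated on, tested on."""

    fold: int
    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]


def make_fold_splits(patients: list[str], controls: list[str]) -> list[FoldSplit]:
    """k = n_patients folds; each patient is the test subject exactly once
    and the validation subject exactly once (the next fold's test patient).
    Controls are dealt round-robin into k subsets; the subset matching the
    test patient's index is held out for test, the next for validation."""
    k = len(patients)
    if k < 3:
        raise ValueError(f"need at least 3 patient subjects for the fold design, got {k}")
    control_subsets: list[list[str]] = [[] for _ in range(k)]
    for i, c in enumerate(controls):
        control_subsets[i % k].append(c)
    splits = []
    for i in range(k):
        j = (i + 1) % k  # validation patient / control subset
        test_p, val_p = patients[i], patients[j]
        train_p = [p for p in patients if p not in (test_p, val_p)]
        test_c = control_subsets[i]
        val_c = control_subsets[j]
        train_c = [c for s in range(k) if s not in (i, j) for c in control_subsets[s]]
        splits.append(
            FoldSplit(
                fold=i,
                train_subjects=tuple(train_p + train_c),
                val_subjects=tuple([val_p] + val_c),
                test_subjects=tuple([test_p] + test_c),
            )
        )
    return splits


def _stack(images: list[ScanpathImage], subjects: set[str]):
    sel = [im for im in images if im.subject_id in subjects]
    if not sel:
        return np.empty((0, 1, 1)), np.empty(0), []
    x = np.stack([im.pixels for im in sel])
    y = np.array([im.label for im in sel], dtype=float)
    return x, y, sel


def train_and_predict(
    split: FoldSplit,
    images: list[ScanpathImage],
    config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, ConvNet]:
    """Train one model on a fold and predict its validation + test trials.

    Returns (prediction records, test AUC, trained model).  Records carry
    a ``split`` column ("val"/"test") so the hybrid combiner can fit its
    weights on validation predictions only.
    """
    config = config or ModelConfig()
    encoders = {im.encoder for im in images}
    ms = {im.m for im in images}
    if len(encoders) != 1 or len(ms) != 1:
        raise ValueError("images must share one encoder and one m")
    encoder = next(iter(encoders))
    x_tr, y_tr, _ = _stack(images, set(split.train_subjects))
    x_va, y_va, img_va = _stack(images, set(split.val_subjects))
    x_te, y_te, img_te = _stack(images, set(split.test_subjects))
    if len(np.unique(y_tr)) < 2:
        raise ValueError(f"fold {split.fold}: training set contains a single class")
    net = ConvNet(x_tr.shape[1:], channels=config.channels, seed=seed)
    net.fit(x_tr, y_tr, x_va, y_va, config.train_config(seed))
    rows = []
    for tag, imgs, probs in (
        ("val", img_va, net.predict(x_va) if len(img_va) else []),
        ("test", img_te, net.predict(x_te) if len(img_te) else []),
    ):
        for im, p in zip(imgs, probs):
            rows.append((split.fold, encoder.value, tag, im.subject_id, im.trial_id,
                         im.label, float(p)))
    records = pd.DataFrame(
        rows, columns=["fold", "encoder", "split", "subject", "trial", "label", "probability"]
    )
    test = records[records["split"] == "test"]
    auc = (
        roc_auc_score(test["label"], test["probability"])
        if test["label"].nunique() == 2
        else np.nan
    )
    return records, float(auc), net


def repeat_runs(
    split: FoldSplit,
    images: list[ScanpathImage],
    config: ModelConfig | None = None,
    n_rep: int = 10,
    seed: int = 0,
) -> dict:
    """Repeat train/test ``n_rep`` times with fresh initializations and
    trial orders; report per-repetition AUCs, their mean and sd, and the
    pooled prediction records (one test prediction per trial per rep)."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(split.fold,))
    rep_seeds = ss.generate_state(n_rep) % (2**31)
    all_records = []
    aucs = []
    models = []
    for rep in range(n_rep):
        records, auc, net = train_and_predict(split, images, config, seed=int(rep_seeds[rep]))
        records = records.assign(repetition=rep)
        all_records.append(records)
        aucs.append(auc)
        models.append(net)
    aucs = np.array(aucs, dtype=float)
    return {
        "records": pd.concat(all_records, ignore_index=True),
        "aucs": aucs,
        "mean_auc": float(np.nanmean(aucs)),
        "sd_auc": float(np.nanstd(aucs)) if n_rep > 1 else 0.0,
        "models": models,
    }
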