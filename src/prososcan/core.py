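"""Fixation/trial data model, the 10-region face template, tabular I/O.

Coordinates are image-frame pixels: origin at the top-left of the screen,
x increasing rightward, y increasing downward.  "Left eye" always means the
eye on the left side of the *image* (the photographed person's right eye).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Group",
    "Phase",
    "Fixation",
    "Trial",
    "FaceTemplate",
    "Cohort",
    "ROI_NAMES",
    "SchemaError",
    "ValidationError",
    "assign_roi",
    "load_trials",
    "filter_min_fixations",
    "distance_from_center",
]

#: Canonical ROI codes.  1=left eye, 2=right eye, 3=left eyebrow,
#: 4=right eyebrow, 5=left cheek, 6=right cheek, 7=forehead, 8=nose,
#: 9=mouth, 10=chin.  "Left"/"right" refer to image space.
ROI_NAMES: dict[int, str] = {
    1: "left_eye",
    2: "right_eye",
    3: "left_eyebrow",
    4: "right_eyebrow",
    5: "left_cheek",
    6: "right_cheek",
    7: "forehead",
    8: "nose",
    9: "mouth",
    10: "chin",
}

REQUIRED_COLUMNS = ("subject", "group", "phase", "trial", "order", "x", "y", "duration_ms")


class SchemaError(ValueError):
    """A fixation table is missing required columns."""


class ValidationError(ValueError):
    """A fixation table row violates a value constraint."""


class Group(str, enum.Enum):
    CONTROL = "control"
    ACQUIRED = "acquired"
    DEVELOPMENTAL = "developmental"

    @property
    def label(self) -> int:
        """Binary class label: 0 for controls, 1 for either patient group."""
        return 0 if self is Group.CONTROL else 1


class Phase(str, enum.Enum):
    LEARNING = "learning"
    RECOGNITION = "recognition"


@dataclass(frozen=True)
class Fixation:
    """A single fixation: position (px), duration (ms), ROI code, order."""

    x: float
    y: float
    duration: float
    roi: int
    order: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"non-finite fixation coordinates ({self.x}, {self.y})")
        if self.duration < 0:
            raise ValidationError(f"negative fixation duration {self.duration}")
        if not 1 <= int(self.roi) <= 10:
            raise ValidationError(f"ROI code {self.roi} outside 1..10")
        if self.order < 1:
            raise ValidationError(f"fixation order {self.order} must be >= 1")


@dataclass
class Trial:
    """An ordered fixation sequence with subject/group/phase metadata."""

    subject_id: str
    group: Group
    phase: Phase
    trial_id: str
    fixations: list[Fixation]
    correct: bool | None = None

    def __post_init__(self) -> None:
        if not self.fixations:
            raise ValidationError(f"trial {self.trial_id!r} of {self.subject_id!r} has no fixations")
        orders = [f.order for f in self.fixations]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ValidationError(f"fixation order not strictly increasing in trial {self.trial_id!r}")

    def __len__(self) -> int:
        return len(self.fixations)

    @property
    def label(self) -> int:
        return self.group.label

    def roi_sequence(self, m: int | None = None) -> np.ndarray:
        codes = np.array([f.roi for f in self.fixations], dtype=int)
        return codes if m is None else codes[:m]


@dataclass
class FaceTemplate:
    """Rectangular ROI layout on a fixed stimulus frame.

    Regions are axis-aligned boxes ``(x0, y0, x1, y1)`` with inclusive
    edges; points covered by several boxes (shared edges) resolve to the
    lowest ROI code.  Points outside every box map to the nearest anchor.
    """

    width: int
    height: int
    regions: dict[int, tuple[float, float, float, float]]
    anchors: dict[int, tuple[float, float]]
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if sorted(self.regions) != list(range(1, 11)) or sorted(self.anchors) != list(range(1, 11)):
            raise ValidationError("template must define regions and anchors for ROI codes 1..10")
        # cache arrays for vectorized assignment (code order 1..10)
        self._boxes = np.array([self.regions[c] for c in range(1, 11)], dtype=float)
        self._anchor_xy = np.array([self.anchors[c] for c in range(1, 11)], dtype=float)

    # -- geometry ----------------------------------------------------------

    def assign(self, x, y) -> np.ndarray:
        """Vectorized ROI assignment for coordinate arrays (see assign_roi)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("non-finite coordinates passed to ROI assignment")
        b = self._boxes
        inside = (
            (x[:, None] >= b[None, :, 0])
            & (x[:, None] <= b[None, :, 2])
            & (y[:, None] >= b[None, :, 1])
            & (y[:, None] <= b[None, :, 3])
        )
        any_inside = inside.any(axis=1)
        codes = np.empty(x.shape, dtype=int)
        # lowest containing code wins on shared edges
        codes[any_inside] = inside[any_inside].argmax(axis=1) + 1
        if not any_inside.all():
            out = ~any_inside
            d2 = (x[out, None] - self._anchor_xy[None, :, 0]) ** 2 + (
                y[out, None] - self._anchor_xy[None, :, 1]
            ) ** 2
            codes[out] = d2.argmin(axis=1) + 1  # argmin takes lowest code on ties
        return codes

    def anchor(self, roi: int) -> tuple[float, float]:
        return self.anchors[roi]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "center": list(self.center),
            "regions": {ROI_NAMES[c]: list(self.regions[c]) for c in range(1, 11)},
            "anchors": {ROI_NAMES[c]: list(self.anchors[c]) for c in range(1, 11)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FaceTemplate":
        name_to_code = {v: k for k, v in ROI_NAMES.items()}

        def _keyed(section: Mapping) -> dict:
            out = {}
            for key, val in section.items():
                code = name_to_code[key] if key in name_to_code else int(key)
                out[code] = tuple(float(v) for v in val)
            return out

        return cls(
            width=int(d["width"]),
            height=int(d["height"]),
            regions=_keyed(d["regions"]),
            anchors=_keyed(d["anchors"]),
            center=tuple(float(v) for v in d["center"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FaceTemplate":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "FaceTemplate":
        """Canonical template: 1024x768 frame, face box 300x400 centered.

        Eyes/eyebrows in the upper third of the face box, cheeks flanking
        the nose in the middle band, mouth and chin below.  The nose anchor
        sits at the frame center (stimuli were presented nose-centered).
        """
        cx, cy = 512.0, 384.0
        x0, x1 = cx - 150, cx + 150  # 362..662
        y0, y1 = cy - 200, cy + 200  # 184..584
        xm = cx
        nose_x0, nose_x1 = cx - 75, cx + 75
        brow_y0, brow_y1 = y0 + 67, y0 + 100  # 251..284
        eye_y1 = y0 + 133  # ..317
        mid_y1 = cy + 67  # ..451
        mouth_y1 = cy + 133  # ..517
        regions = {
            1: (x0, brow_y1, xm, eye_y1),  # left eye
            2: (xm, brow_y1, x1, eye_y1),  # right eye
            3: (x0, brow_y0, xm, brow_y1),  # left eyebrow
            4: (xm, brow_y0, x1, brow_y1),  # right eyebrow
            5: (x0, eye_y1, nose_x0, mid_y1),  # left cheek
            6: (nose_x1, eye_y1, x1, mid_y1),  # right cheek
            7: (x0, y0, x1, brow_y0),  # forehead
            8: (nose_x0, eye_y1, nose_x1, mid_y1),  # nose
            9: (x0, mid_y1, x1, mouth_y1),  # mouth
            10: (x0, mouth_y1, x1, y1),  # chin
        }
        anchors = {c: ((r[0] + r[2]) / 2, (r[1] + r[3]) / 2) for c, r in regions.items()}
        return cls(width=1024, height=768, regions=regions, anchors=anchors, center=(cx, cy))


def assign_roi(x: float, y: float, template: FaceTemplate) -> int:
    """Map a fixation position to its ROI code.

    Returns the code of the containing region; shared edges resolve to the
    lowest code.  Off-face points map to the nearest region anchor, ties
    again to the lowest code.
    """
    return int(template.assign(x, y)[0])


def distance_from_center(fixation: Fixation, template: FaceTemplate) -> float:
    """Euclidean distance (px) of a fixation from the face center."""
    cx, cy = template.center
    return float(np.hypot(fixation.x - cx, fixation.y - cy))


@dataclass
class Cohort:
    """A set of trials plus the subject roster behind them."""

    trials: list[Trial]
    subjects: pd.DataFrame = field(default=None)  # columns: subject, group

    def __post_init__(self) -> None:
        if self.subjects is None:
            rows = sorted({(t.subject_id, t.group.value) for t in self.trials})
            self.subjects = pd.DataFrame(rows, columns=["subject", "group"])
        known = set(self.subjects["subject"])
        for t in self.trials:
            if t.subject_id not in known:
                raise ValidationError(f"trial subject {t.subject_id!r} missing from roster")
        groups = dict(zip(self.subjects["subject"], self.subjects["group"]))
        for t in self.trials:
            if groups[t.subject_id] != t.group.value:
                raise ValidationError(f"subject {t.subject_id!r} has inconsistent group labels")

    def __len__(self) -> int:
        return len(self.trials)

    def subject_ids(self, group: Group | None = None) -> list[str]:
        df = self.subjects
        if group is not None:
            df = df[df["group"] == group.value]
        return list(df["subject"])

    def group_counts(self) -> pd.Series:
        return self.subjects["group"].value_counts()

    def trials_of(self, subject_id: str) -> list[Trial]:
        return [t for t in self.trials if t.subject_id == subject_id]

    def to_frame(self) -> pd.DataFrame:
        """Flatten back to one row per fixation (round-trips load_trials)."""
        rows = []
        for t in self.trials:
            for f in t.fixations:
                rows.append(
                    (t.subject_id, t.group.value, t.phase.value, t.trial_id,
                     f.order, f.x, f.y, f.duration, f.roi,
                     "" if t.correct is None else int(t.correct))
                )
        return pd.DataFrame(
            rows, columns=list(REQUIRED_COLUMNS) + ["roi", "correct"]
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def relabeled(self, mapping: Mapping[str, Group]) -> "Cohort":
        """New cohort with subjects re-assigned to groups (used by the
        subject-level permutation test)."""
        trials = [
            Trial(t.subject_id, mapping[t.subject_id], t.phase, t.trial_id,
                  t.fixations, t.correct)
            for t in self.trials
        ]
        roster = pd.DataFrame(
            {"subject": self.subjects["subject"],
             "group": [mapping[s].value for s in self.subjects["subject"]]}
        )
        return Cohort(trials, roster)


def load_trials(table: pd.DataFrame | str | Path, template: FaceTemplate | None = None) -> Cohort:
    """Build a Cohort from a fixation table (one row per fixation).

    Required columns: subject, group, phase, trial, order, x, y,
    duration_ms.  The ``roi`` column is optional and derived from the
    template geometry when absent; ``correct`` is optional trial accuracy.
    """
    if not isinstance(table, pd.DataFrame):
        path = Path(table)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        table = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"fixation table missing required columns: {missing}")
    df = table.copy()
    if len(df) == 0:
        return Cohort(trials=[], subjects=pd.DataFrame(columns=["subject", "group"]))
    if "roi" not in df.columns or df["roi"].isna().all():
        if template is None:
            template = FaceTemplate.default()
        df["roi"] = template.assign(df["x"].to_numpy(float), df["y"].to_numpy(float))
    else:
        roi = pd.to_numeric(df["roi"], errors="coerce")
        bad = df.index[~roi.isin(range(1, 11))]
        if len(bad):
            raise ValidationError(
                f"row {bad[0]}: ROI code {df.loc[bad[0], 'roi']!r} outside 1..10"
            )
        df["roi"] = roi.astype(int)

    trials: list[Trial] = []
    for (subject, trial_id), g in df.groupby(["subject", "trial"], sort=True):
        g = g.sort_values("order")
        group = Group(str(g["group"].iloc[0]))
        phase = Phase(str(g["phase"].iloc[0]))
        correct = None
        if "correct" in g.columns and pd.notna(g["correct"].iloc[0]) and g["correct"].iloc[0] != "":
            correct = bool(int(g["correct"].iloc[0]))
        fixations = [
            Fixation(x=float(r.x), y=float(r.y), duration=float(r.duration_ms),
                     roi=int(r.roi), order=int(r.order))
            for r in g.itertuples()
        ]
        trials.append(Trial(str(subject), group, phase, str(trial_id), fixations, correct))
    return Cohort(trials)


def filter_min_fixations(cohort: Cohort, m: int) -> Cohort:
    """Keep only trials with at least ``m`` fixations (1 < m <= 20)."""
    if not 1 < m <= 20:
        raise ValueError(f"m must satisfy 1 < m <= 20, got {m}")
    kept = [t for t in cohort.trials if len(t) >= m]
    return Cohort(kept, cohort.subjects.copy())
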