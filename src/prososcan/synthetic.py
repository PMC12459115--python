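"""Synthetic scanpath cohorts with planted group structure.

Each cohort group is described by a :class:`GroupProfile`: a first-order
Markov chain over the 10 face ROIs drives the fixation sequence, fixation
positions are the visited ROI's anchor plus isotropic Gaussian jitter,
durations are i.i.d. log-normal, and trial lengths follow a shifted
negative binomial so that prefix filtering at m fixations discards a
realistic fraction of trials.  Per-subject idiosyncrasy enters as Gaussian
noise on the transition-matrix logits.

The three presets plant the group contrasts the downstream analysis is
designed to detect: controls concentrate early fixations on the nose and
then the eyes with a left-image-eye bias; acquired prosopagnosia shifts
mass to the mouth/nose and the right-image eye; developmental
prosopagnosia is control-like in feature preference but spatially more
dispersed toward peripheral regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import Cohort, FaceTemplate, Fixation, Group, Phase, Trial

__all__ = ["GroupProfile", "generate_trial", "generate_cohort", "preset_profiles"]

_N_ROI = 10


@dataclass
class GroupProfile:
    """Generative parameters for one cohort group's scanpaths."""

    name: Group
    roi_transition: np.ndarray  # (10, 10) row-stochastic
    initial_roi_distribution: np.ndarray  # (10,)
    spatial_jitter_sd: float  # px
    duration_lognormal: tuple[float, float]  # (mu, sigma) in log-ms
    n_fixations_nb: tuple[float, float]  # negative binomial (size r, prob p)
    n_fixations_shift: int = 1  # trial length = shift + NB(r, p), so >= shift
    trials_per_subject: int = 45
    learning_trials: int = 10
    subject_heterogeneity_sd: float = 0.0

    def __post_init__(self) -> None:
        self.roi_transition = np.asarray(self.roi_transition, dtype=float)
        self.initial_roi_distribution = np.asarray(self.initial_roi_distribution, dtype=float)
        if self.roi_transition.shape != (_N_ROI, _N_ROI):
            raise ValueError("roi_transition must be 10x10")
        if np.any(self.roi_transition < 0) or np.any(self.initial_roi_distribution < 0):
            raise ValueError("transition/initial probabilities must be nonnegative")
        if not np.allclose(self.roi_transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("roi_transition rows must sum to 1")
        if not np.isclose(self.initial_roi_distribution.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_roi_distribution must sum to 1")
        if self.spatial_jitter_sd < 0:
            raise ValueError("spatial_jitter_sd must be >= 0")
        r, p = self.n_fixations_nb
        if r <= 0 or not 0 < p <= 1:
            raise ValueError("n_fixations_nb needs size > 0 and 0 < prob <= 1")
        if self.n_fixations_shift < 1:
            raise ValueError("n_fixations_shift must be >= 1 (trials cannot be empty)")
        mu, sigma = self.duration_lognormal
        if sigma < 0:
            raise ValueError("duration sigma must be >= 0")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name.value,
            "roi_transition": self.roi_transition.tolist(),
            "initial_roi_distribution": self.initial_roi_distribution.tolist(),
            "spatial_jitter_sd": self.spatial_jitter_sd,
            "duration_lognormal": list(self.duration_lognormal),
            "n_fixations_nb": list(self.n_fixations_nb),
            "n_fixations_shift": self.n_fixations_shift,
            "trials_per_subject": self.trials_per_subject,
            "learning_trials": self.learning_trials,
            "subject_heterogeneity_sd": self.subject_heterogeneity_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupProfile":
        return cls(
            name=Group(d["name"]),
            roi_transition=np.asarray(d["roi_transition"], dtype=float),
            initial_roi_distribution=np.asarray(d["initial_roi_distribution"], dtype=float),
            spatial_jitter_sd=float(d["spatial_jitter_sd"]),
            duration_lognormal=tuple(d["duration_lognormal"]),
            n_fixations_nb=tuple(d["n_fixations_nb"]),
            n_fixations_shift=int(d.get("n_fixations_shift", 1)),
            trials_per_subject=int(d.get("trials_per_subject", 45)),
            learning_trials=int(d.get("learning_trials", 10)),
            subject_heterogeneity_sd=float(d.get("subject_heterogeneity_sd", 0.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _perturb_transition(transition: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Subject-specific transition matrix: Gaussian noise on row logits."""
    if sd == 0:
        return transition
    logits = np.log(transition + 1e-12) + rng.normal(0.0, sd, size=transition.shape)
    mat = np.exp(logits - logits.max(axis=1, keepdims=True))
    return mat / mat.sum(axis=1, keepdims=True)


def generate_trial(
    profile: GroupProfile,
    rng: np.random.Generator,
    template: FaceTemplate | None = None,
    subject_id: str = "S1",
    trial_id: str = "T1",
    phase: Phase = Phase.RECOGNITION,
    transition: np.ndarray | None = None,
) -> Trial:
    """Draw one trial from a profile (optionally a subject-perturbed chain).

    The ROI sequence is a Markov chain; each fixation lands at its ROI's
    anchor plus isotropic Gaussian jitter and is then *re-assigned* an ROI
    from its jittered position, so recorded codes can disagree with the
    latent chain state near region borders, as with real data.
    """
    if template is None:
        template = FaceTemplate.default()
    trans = profile.roi_transition if transition is None else transition
    r, p = profile.n_fixations_nb
    n = profile.n_fixations_shift + int(rng.negative_binomial(r, p))
    # inverse-CDF sampling of the chain (cheaper than rng.choice per step)
    cum_init = np.cumsum(profile.initial_roi_distribution)
    cum_trans = np.cumsum(trans, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=int)
    states[0] = min(int(np.searchsorted(cum_init, u[0], side="right")), _N_ROI - 1)
    for k in range(1, n):
        states[k] = min(int(np.searchsorted(cum_trans[states[k - 1]], u[k], side="right")), _N_ROI - 1)
    anchors = np.array([template.anchor(s + 1) for s in states], dtype=float)
    xy = anchors + rng.normal(0.0, profile.spatial_jitter_sd, size=(n, 2))
    xy[:, 0] = np.clip(xy[:, 0], 0, template.width - 1)
    xy[:, 1] = np.clip(xy[:, 1], 0, template.height - 1)
    rois = template.assign(xy[:, 0], xy[:, 1])
    mu, sigma = profile.duration_lognormal
    durations = rng.lognormal(mu, sigma, size=n)
    fixations = [
        Fixation(x=float(xy[k, 0]), y=float(xy[k, 1]), duration=float(durations[k]),
                 roi=int(rois[k]), order=k + 1)
        for k in range(n)
    ]
    return Trial(subject_id, profile.name, phase, trial_id, fixations)


def generate_cohort(
    n_subjects: int,
    profile: GroupProfile,
    seed: int | np.random.Generator = 0,
    template: FaceTemplate | None = None,
    subject_prefix: str | None = None,
) -> Cohort:
    """Generate ``n_subjects`` subjects' worth of trials from one profile.

    Deterministic for a fixed seed.  The first ``learning_trials`` trials
    per subject are tagged as the learning phase, the rest as recognition.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if template is None:
        template = FaceTemplate.default()
    prefix = subject_prefix or {
        Group.CONTROL: "C", Group.ACQUIRED: "AP", Group.DEVELOPMENTAL: "DP"
    }[profile.name]
    trials: list[Trial] = []
    for s in range(n_subjects):
        sid = f"{prefix}{s + 1:02d}"
        trans = _perturb_transition(profile.roi_transition, profile.subject_heterogeneity_sd, rng)
        for t in range(profile.trials_per_subject):
            phase = Phase.LEARNING if t < profile.learning_trials else Phase.RECOGNITION
            trials.append(
                generate_trial(profile, rng, template, subject_id=sid,
                               trial_id=f"T{t + 1:03d}", phase=phase, transition=trans)
            )
    return Cohort(trials)


def _rank_one_chain(attraction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All rows equal to the attraction vector: a valid Markov matrix whose
    marginal visit rates equal the attraction weights."""
    a = np.asarray(attraction, dtype=float)
    a = a / a.sum()
    return np.tile(a, (_N_ROI, 1)), a


# Attraction weights over [Leye, Reye, Lbrow, Rbrow, Lcheek, Rcheek,
# forehead, nose, mouth, chin].  Magnitudes are calibrated so the planted
# contrasts are of the order the analysis reports on real data (e.g. the
# control preset's expected left:right index is (0.30-0.17)/0.47 = +0.28).
_CONTROL_ATTRACTION = [0.32, 0.18, 0.03, 0.02, 0.02, 0.02, 0.03, 0.24, 0.10, 0.04]
_ACQUIRED_ATTRACTION = [0.04, 0.18, 0.02, 0.05, 0.02, 0.04, 0.04, 0.30, 0.28, 0.03]
_DEVELOPMENTAL_ATTRACTION = [0.18, 0.12, 0.06, 0.05, 0.06, 0.06, 0.07, 0.22, 0.10, 0.08]

# First fixation lands on the nose for every group (nose-centered stimuli).
_INITIAL = [0.03, 0.03, 0.01, 0.01, 0.02, 0.02, 0.03, 0.78, 0.05, 0.02]


def preset_profiles(
    trials_per_subject: int = 45,
    subject_heterogeneity_sd: float = 0.2,
) -> dict[str, GroupProfile]:
    """The three study-condition profiles keyed by group name.

    Trial length = 1 + NegBinom(r=10, p=10/29): mean 20 fixations with
    enough spread that prefix filtering at m=16 keeps roughly 70% of
    trials while the m-sweep still sees attrition at every m > 2.
    Durations are log-normal with median ~230 ms and mean ~250 ms.
    """
    nb = (10.0, 10.0 / 29.0)
    dur = (float(np.log(250.0) - 0.5 * 0.4**2), 0.4)
    common = dict(
        duration_lognormal=dur,
        n_fixations_nb=nb,
        trials_per_subject=trials_per_subject,
        subject_heterogeneity_sd=subject_heterogeneity_sd,
    )
    control_T, _ = _rank_one_chain(np.array(_CONTROL_ATTRACTION))
    acquired_T, _ = _rank_one_chain(np.array(_ACQUIRED_ATTRACTION))
    dev_T, _ = _rank_one_chain(np.array(_DEVELOPMENTAL_ATTRACTION))
    init = np.array(_INITIAL) / np.sum(_INITIAL)
    return {
        "control": GroupProfile(
            name=Group.CONTROL, roi_transition=control_T,
            initial_roi_distribution=init, spatial_jitter_sd=22.0, **common),
        "acquired": GroupProfile(
            name=Group.ACQUIRED, roi_transition=acquired_T,
            initial_roi_distribution=init, spatial_jitter_sd=22.0, **common),
        "developmental": GroupProfile(
            name=Group.DEVELOPMENTAL, roi_transition=dev_T,
            initial_roi_distribution=init, spatial_jitter_sd=45.0, **common),
    }


def two_group_cohort(
    profile_a: GroupProfile,
    profile_b: GroupProfile,
    n_a: int,
    n_b: int,
    seed: int = 0,
    template: FaceTemplate | None = None,
) -> Cohort:
    """Convenience: one cohort holding two groups drawn with a shared seed
    stream (subject prefixes come from the profile group names)."""
    rng = np.random.default_rng(seed)
    ca = generate_cohort(n_a, profile_a, rng, template)
    cb = generate_cohort(n_b, profile_b, rng, template)
    return Cohort(ca.trials + cb.trials, pd.concat([ca.subjects, cb.subjects], ignore_index=True))
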