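from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from prososcan import FaceTemplate, Fixation, Group, Phase, Trial


@pytest.fixture(scope="session")
def template() -> FaceTemplate:
    return FaceTemplate.default()


def make_trial(
    rois,
    subject="S1",
    group=Group.CONTROL,
    trial_id="T1",
    template=None,
    durations=None,
    xy=None,
    phase=Phase.RECOGNITION,
):
    """Build a trial whose fixations sit at the ROI anchors (or given xy)."""
    template = template or FaceTemplate.default()
    fixations = []
    for k, roi in enumerate(rois, start=1):
        if xy is not None:
            x, y = xy[k - 1]
        else:
            x, y = template.anchor(roi)
        d = 250.0 if durations is None else durations[k - 1]
        fixations.append(Fixation(x=x, y=y, duration=d, roi=roi, order=k))
    return Trial(subject, group, phase, trial_id, fixations)


@pytest.fixture
def trial_factory():
    return make_trial


@pytest.fixture
def fixation_frame() -> pd.DataFrame:
    """A small two-subject fixation table."""
    rows = []
    for subj, group, rois in [
        ("S1", "control", [8, 1, 2, 9]),
        ("P1", "acquired", [8, 9, 9]),
    ]:
        tpl = FaceTemplate.default()
        for k, roi in enumerate(rois, start=1):
            x, y = tpl.anchor(roi)
            rows.append((subj, group, "recognition", "T1", k, x, y, 200.0, roi))
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "phase", "trial", "order", "x", "y", "duration_ms", "roi"],
    )
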