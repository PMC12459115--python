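"""Packaged reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_recognition_scores"]


def load_recognition_scores() -> pd.DataFrame:
    """Published recognition-task signal-detection scores for the study
    cohort: per-subject d' (sensitivity) and c (criterion bias) for the 8
    acquired prosopagnosic, 10 developmental prosopagnosic and 20 control
    subjects.  Columns: subject, group, dprime, criterion.
    """
    with resources.files("prososcan.data").joinpath("recognition_scores.csv").open() as fh:
        return pd.read_csv(fh)
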