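"""Readers for the delimited text formats the command-line tools accept.

All files are header-first delimited text (comma or tab, autodetected).
Labels are coded 0 for actually-negative and 1 for actually-positive
subjects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .auc_nonparametric import PairedScoreSample, ScoreSample
from .ideal_auc_ftest import TwoClassData

__all__ = ["load_scores", "load_paired_scores", "load_biomarker_table"]


def _read_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def _labels(frame: pd.DataFrame, path: str | Path) -> np.ndarray:
    if "label" not in frame.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    labels = frame["label"].to_numpy()
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError(f"{path}: labels must be coded 0 (negative) / 1 (positive)")
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ValueError(f"{path}: both classes must be present")
    return labels.astype(bool)


def load_scores(path: str | Path) -> ScoreSample:
    """Read a single-model score file with columns ``label`` and ``score``."""
    frame = _read_table(path)
    if "score" not in frame.columns:
        raise ValueError(f"{path}: missing required 'score' column")
    positive = _labels(frame, path)
    scores = frame["score"].to_numpy(dtype=float)
    return ScoreSample(neg_scores=scores[~positive], pos_scores=scores[positive])


def load_paired_scores(path: str | Path) -> PairedScoreSample:
    """Read a paired-score file with columns ``label``, ``score1``, ``score2``."""
    frame = _read_table(path)
    for col in ("score1", "score2"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required '{col}' column")
    positive = _labels(frame, path)
    s1 = frame["score1"].to_numpy(dtype=float)
    s2 = frame["score2"].to_numpy(dtype=float)
    return PairedScoreSample(
        neg_scores_1=s1[~positive],
        neg_scores_2=s2[~positive],
        pos_scores_1=s1[positive],
        pos_scores_2=s2[positive],
    )


def load_biomarker_table(path: str | Path) -> tuple[TwoClassData, list[str]]:
    """Read a biomarker table (``label`` + one numeric column per biomarker).

    Returns the two-class data and the biomarker column names in file
    order, for resolving user-supplied column-name index sets.
    """
    frame = _read_table(path)
    positive = _labels(frame, path)
    columns = [c for c in frame.columns if c != "label"]
    if not columns:
        raise ValueError(f"{path}: no biomarker columns found")
    matrix = frame[columns].to_numpy(dtype=float)
    data = TwoClassData(neg_matrix=matrix[~positive], pos_matrix=matrix[positive])
    return data, columns
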