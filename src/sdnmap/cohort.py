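"""Cohort-level domain containers.

A study is a list of :class:`SubjectSeries` (one per participant: serial
volume-change maps plus nuisance covariates) and a list of
:class:`CognitiveRecord` (serial neuropsychological scores). These are the
atomic inputs of the pipeline, whether simulated or loaded from disk.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

GROUPS = ("HC", "MCIs", "MCIp", "AD")
"""Study groups: healthy controls, stable MCI, MCI progressing to dementia, AD."""

COVARIATE_NAMES = ("age", "sex", "education", "tiv")
"""Nuisance covariates used in every group-level model."""

COGNITIVE_TESTS = ("MMSE", "CVVLT", "CFT_copy", "CFT_recall", "VFT", "BNT", "TMT_B")


@dataclass
class SubjectSeries:
    """One subject's serial volume-change maps and covariates.

    ``maps[t]`` is a 3-D map on ``grid`` at acquisition time ``times[t]``
    (years from the subject's first scan). Map values are on a relative
    volume scale (Jacobian-determinant-like): 1 means no change, <1 local
    contraction.
    """

    subject_id: str
    group: str
    covariates: dict[str, float]
    times: np.ndarray
    maps: list[np.ndarray]
    grid: Grid

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.maps):
            raise ValueError("times and maps must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points per subject")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        self.maps = [self.grid.check_data(m) for m in self.maps]
        missing = [c for c in COVARIATE_NAMES if c not in self.covariates]
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing covariates {missing}")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)


@dataclass
class CognitiveRecord:
    """Serial scores of one neuropsychological test for one subject."""

    subject_id: str
    test_name: str
    times: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.test_name not in COGNITIVE_TESTS:
            raise ValueError(f"unknown test {self.test_name!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.times.shape != self.scores.shape:
            raise ValueError("times and scores must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least 2 score time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("score times must be strictly increasing")


def covariate_table(subjects: list[SubjectSeries]):
    """Covariates of a cohort as a pandas DataFrame indexed by subject id."""
    import pandas as pd

    rows = {s.subject_id: {"group": s.group, **s.covariates} for s in subjects}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
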