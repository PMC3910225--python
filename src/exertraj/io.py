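"""Cohort CSV readers/writers and result serialization.

The long-format cohort CSV has one row per rating with columns
``subject_id``, ``rating``, and either ``work_frac`` or the pair
``work_abs`` + ``wmax`` (work in kpm/min, normalized on read).  Optional
columns: ``step``, ``age``, ``sex``, ``diagnosis``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SubjectTrajectory

__all__ = [
    "CohortFormatError",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frame",
]

_COVARIATE_COLS = ("age", "sex", "diagnosis")


class CohortFormatError(ValueError):
    """Malformed cohort file; carries per-row problem reports."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def read_cohort_csv(path: "str | Path") -> list[SubjectTrajectory]:
    """Read a long-format cohort CSV into trajectories.

    Rows are grouped by subject and sorted by work fraction; problems are
    reported with 1-based data line numbers (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    problems: list[str] = []

    if "subject_id" not in frame.columns:
        raise CohortFormatError(["missing required column 'subject_id'"])
    if "rating" not in frame.columns:
        raise CohortFormatError(["missing required column 'rating'"])
    if "work_frac" in frame.columns:
        work = frame["work_frac"].astype(float)
    elif "work_abs" in frame.columns and "wmax" in frame.columns:
        work = frame["work_abs"].astype(float) / frame["wmax"].astype(float)
    else:
        raise CohortFormatError(
            ["missing required column 'work_frac' (or 'work_abs' + 'wmax')"]
        )
    frame = frame.assign(_work=work)

    lineno = frame.index + 2  # header occupies line 1
    bad_rating = (frame["rating"] < 0) | (frame["rating"] > 10)
    for ln, val in zip(lineno[bad_rating], frame.loc[bad_rating, "rating"]):
        problems.append(f"line {ln}: rating {val} outside [0, 10]")
    bad_work = (frame["_work"] <= 0) | (frame["_work"] > 1 + 1e-9)
    for ln, val in zip(lineno[bad_work], frame.loc[bad_work, "_work"]):
        problems.append(f"line {ln}: work fraction {val:g} outside (0, 1]")
    dup = frame.duplicated(subset=["subject_id", "_work"], keep=False)
    for ln, sid in zip(lineno[dup], frame.loc[dup, "subject_id"]):
        problems.append(f"line {ln}: duplicate (subject {sid}, work) pair")
    if problems:
        raise CohortFormatError(problems)

    trajectories = []
    for sid, group in frame.groupby("subject_id", sort=True):
        group = group.sort_values("_work")
        covariates = {}
        for col in _COVARIATE_COLS:
            if col in group.columns and pd.notna(group[col].iloc[0]):
                val = group[col].iloc[0]
                covariates[col] = int(val) if col == "age" else str(val)
        trajectories.append(SubjectTrajectory(
            subject_id=str(sid),
            x=group["_work"].to_numpy(),
            y=group["rating"].to_numpy(),
            covariates=covariates,
        ))
    return trajectories


def cohort_to_frame(cohort: Sequence[SubjectTrajectory]) -> pd.DataFrame:
    rows = []
    for traj in cohort:
        for step, (x, y) in enumerate(zip(traj.x, traj.y), start=1):
            row = {
                "subject_id": traj.subject_id,
                "step": step,
                "work_frac": float(x),
                "rating": float(y),
            }
            for col in _COVARIATE_COLS:
                if col in traj.covariates:
                    row[col] = traj.covariates[col]
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: Sequence[SubjectTrajectory],
                     path: "str | Path") -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def write_json(obj: object, path: "str | Path") -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
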