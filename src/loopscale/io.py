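"""Plain-text table readers/writers for the pipeline's file dialects.

Trajectory files are tab-delimited with one row per sample and a mandatory
header ``participant_id condition trial t_s x_cm y_cm pen_down``; score
files are delimited text with ``participant_id group wellbeing_total
general_depression_total``.  All files are UTF-8 with '.' decimal separator.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import FormatError
from .kinematics import PenTrajectory
from .synthetic import GROUPS

TRAJECTORY_COLUMNS = [
    "participant_id",
    "condition",
    "trial",
    "t_s",
    "x_cm",
    "y_cm",
    "pen_down",
]
SCORE_COLUMNS = [
    "participant_id",
    "group",
    "wellbeing_total",
    "general_depression_total",
]


def write_trajectories(trajs: list[PenTrajectory], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": tr.participant_id,
                "condition": tr.condition,
                "trial": tr.trial,
                "t_s": tr.t,
                "x_cm": tr.x,
                "y_cm": tr.y,
                "pen_down": tr.pen_down,
            }
        )
        for tr in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_trajectories(path: str | Path) -> list[PenTrajectory]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory file {path} missing columns {missing}")
    trajs = []
    for (pid, cond, trial), grp in df.groupby(
        ["participant_id", "condition", "trial"], sort=True
    ):
        trajs.append(
            PenTrajectory(
                participant_id=str(pid),
                condition=str(cond),
                trial=int(trial),
                t=grp["t_s"].to_numpy(float),
                x=grp["x_cm"].to_numpy(float),
                y=grp["y_cm"].to_numpy(float),
                pen_down=grp["pen_down"].to_numpy(int),
            )
        )
    return trajs


def write_scores(records: pd.DataFrame, path: str | Path) -> None:
    records[SCORE_COLUMNS].to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"score file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"score file {path} missing columns {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"score file {path} has unknown group labels {bad}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis table as TSV (the pipeline's exchange format)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")
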