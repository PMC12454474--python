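"""Per-participant velocity-scaling (VS) slopes.

The VS slope is the participant's coefficient on the condition dummy in an
ordinary least-squares regression of per-stroke Peak Vertical Velocity on
Condition (small condition = 0, large = 1) with Vertical Size as covariate,
pooled over all segments of all valid trials of a design:

    peak_velocity ~ 1 + condition_dummy + vertical_size

Designs: ``LL`` contrasts the 1 cm (0) and 4 cm (1) loop conditions;
``LLee`` contrasts the small "ee" (0) and large "LL" (1) strokes of the
mixed condition.  Steeper (more positive) slopes mean stronger velocity
scaling, i.e. less psychomotor slowing.  The dummy and the size covariate
are strongly collinear by construction (size is what differs between
conditions); this is tolerated deliberately — the condition coefficient is
the carried-forward statistic — with a warning when the design matrix
condition number is extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    CollinearityError,
    DegenerateSampleError,
    MissingConditionError,
)
from .kinematics import analysis_strokes

log = logging.getLogger(__name__)

DESIGNS = ("LL", "LLee")
#: dummy coding per design: level -> 0/1 (reference is the smaller condition)
DESIGN_LEVELS = {"LL": {"LL1": 0.0, "LL4": 1.0}, "LLee": {"ee": 0.0, "LL": 1.0}}
MIN_SEGMENTS_FOR_FIT = 4
CONDITION_NUMBER_WARN = 1e4


@dataclass
class VSResult:
    """Velocity-scaling fit for one participant and design."""

    participant_id: str
    design: str
    slope: float  # cm/s per condition step (condition-dummy coefficient)
    intercept: float  # cm/s
    size_coefficient: float  # (cm/s)/cm
    n_segments: int
    slope_z: float = np.nan


def compute_vs(
    peaks: np.ndarray,
    dummy: np.ndarray,
    sizes: np.ndarray,
    participant_id: str = "",
    design: str = "LL",
) -> VSResult:
    """OLS of peak velocity on [1, condition dummy, vertical size].

    Raises
    ------
    MissingConditionError
        If only one condition level is present.
    CollinearityError
        If there is no within-condition size variance (the dummy and the
        size covariate are then perfectly collinear) or too few segments.
    """
    peaks = np.asarray(peaks, float)
    dummy = np.asarray(dummy, float)
    sizes = np.asarray(sizes, float)
    if peaks.size < MIN_SEGMENTS_FOR_FIT:
        raise CollinearityError(
            f"{participant_id or 'participant'}: {peaks.size} segments < "
            f"{MIN_SEGMENTS_FOR_FIT} required for the VS regression"
        )
    levels = np.unique(dummy)
    if levels.size < 2:
        raise MissingConditionError(
            f"{participant_id or 'participant'} ({design}): only condition "
            f"level {levels[0]:g} present; both levels are required"
        )
    within_var = sum(
        np.var(sizes[dummy == lv]) for lv in levels if np.sum(dummy == lv) > 1
    )
    if within_var <= 0:
        raise CollinearityError(
            f"{participant_id or 'participant'} ({design}): vertical size has "
            "no within-condition variance, so the size covariate is perfectly "
            "collinear with the condition dummy; the VS regression is not "
            "identifiable"
        )
    X = np.column_stack([np.ones_like(peaks), dummy, sizes])
    cond = np.linalg.cond(X)
    if cond > CONDITION_NUMBER_WARN:
        log.warning(
            "%s (%s): design-matrix condition number %.3g exceeds %.0e",
            participant_id,
            design,
            cond,
            CONDITION_NUMBER_WARN,
        )
    params, _, rank, _ = np.linalg.lstsq(X, peaks, rcond=None)
    if rank < 3:
        raise CollinearityError(
            f"{participant_id or 'participant'} ({design}): rank-deficient "
            "design matrix"
        )
    return VSResult(
        participant_id=participant_id,
        design=design,
        slope=float(params[1]),
        intercept=float(params[0]),
        size_coefficient=float(params[2]),
        n_segments=int(peaks.size),
    )


def compute_vs_from_strokes(
    strokes: pd.DataFrame, participant_id: str, design: str
) -> VSResult:
    """VS slope for one participant from the long stroke table."""
    levels = DESIGN_LEVELS[design]
    sub = analysis_strokes(strokes)
    sub = sub[
        (sub["participant_id"] == participant_id) & (sub["label"].isin(levels))
    ]
    dummy = sub["label"].map(levels).to_numpy(float)
    return compute_vs(
        sub["peak_velocity_cm_s"].to_numpy(),
        dummy,
        sub["size_cm"].to_numpy(),
        participant_id=participant_id,
        design=design,
    )


def vs_table(
    strokes: pd.DataFrame,
    designs: tuple[str, ...] = DESIGNS,
    llee_participants: set[str] | None = None,
) -> pd.DataFrame:
    """Per-participant VS results for the requested designs.

    Participants for whom a design's regression is infeasible (a missing
    condition level) are skipped with a log entry.  ``llee_participants``
    optionally restricts the LLee design to the retained set from the
    exclusion filter.
    """
    rows = []
    for design in designs:
        ids = sorted(strokes["participant_id"].unique())
        if design == "LLee" and llee_participants is not None:
            ids = [p for p in ids if p in llee_participants]
        for pid in ids:
            try:
                res = compute_vs_from_strokes(strokes, pid, design)
            except (MissingConditionError, CollinearityError) as err:
                log.info("skipping %s for design %s: %s", pid, design, err)
                continue
            rows.append(res.__dict__)
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise DegenerateSampleError("no participant produced a VS fit")
    return zscore_slopes(frame)


def zscore_slopes(vs: pd.DataFrame) -> pd.DataFrame:
    """Standardize slopes to mean 0 / SD 1 across participants, per design."""
    out = vs.copy()
    for design, idx in out.groupby("design").groups.items():
        slopes = out.loc[idx, "slope"].to_numpy(float)
        if slopes.size < 2:
            raise DegenerateSampleError(
                f"design {design}: need >= 2 participants to z-score slopes"
            )
        sd = slopes.std(ddof=1)
        if sd == 0:
            raise DegenerateSampleError(
                f"design {design}: zero slope variance, z-scores undefined"
            )
        out.loc[idx, "slope_z"] = (slopes - slopes.mean()) / sd
    return out


def vs_slopes_batched(
    peaks: np.ndarray, dummy: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized VS regressions for many participants at once.

    ``peaks`` and ``sizes`` are (n_participants, n_segments); ``dummy`` is
    the shared (n_segments,) condition indicator.  Solves each participant's
    3x3 normal equations in one batched call and returns
    ``(slopes, size_coefficients)``.
    """
    n, m = peaks.shape
    ones = np.broadcast_to(np.ones(m), (n, m))
    dums = np.broadcast_to(dummy, (n, m))
    X = np.stack([ones, dums, sizes], axis=-1)  # (n, m, 3)
    XtX = np.einsum("nmi,nmj->nij", X, X)
    Xty = np.einsum("nmi,nm->ni", X, peaks)
    coefs = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    return coefs[:, 1], coefs[:, 2]


def mean_peak_velocity(strokes: pd.DataFrame) -> pd.DataFrame:
    """Average Peak Vertical Velocity per participant and segment class."""
    sub = analysis_strokes(strokes)
    sub = sub[sub["label"] != ""]
    out = (
        sub.groupby(["participant_id", "label"])["peak_velocity_cm_s"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(
            columns={
                "label": "segment_class",
                "mean": "mean_peak_velocity_cm_s",
                "size": "n_segments",
            }
        )
    )
    return out
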