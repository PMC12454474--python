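"""Segment-incremental reliability and VS slope stability.

Internal consistency of Peak Vertical Velocity is assessed with Cronbach's
alpha, treating the k-th valid stroke of a segment class (LL1, LL4, ee, LL)
as the k-th "item" in acquisition order (trial 1 strokes, then trial 2, then
trial 3; 3 trials x 16 strokes = 48 items at most).  Alpha is computed first
for 2 segments (one loop) and re-computed every 2 segments up to 48,
yielding a reliability curve per class.  At each width k only participants
with at least k segments of the class enter (listwise per k; the retained n
is recorded).  Negative alphas are reported as-is, never clipped.

Slope stability recomputes the per-participant VS slope from only the first
k segments per condition and tracks the across-participant mean, SD and the
mean absolute change between consecutive k — the slope has "stabilized"
when that change flattens out.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError, InsufficientDataError
from .kinematics import SEGMENT_CLASSES, analysis_strokes
from .scaling import DESIGN_LEVELS, compute_vs
from .exceptions import CollinearityError, MissingConditionError

log = logging.getLogger(__name__)

DEFAULT_STEP = 2
DEFAULT_MAX_SEGMENTS = 48
MIN_ROWS_FOR_ALPHA = 3


def cronbach_alpha(matrix: np.ndarray) -> float:
    """Cronbach's alpha of a (participants x items) matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / var(row totals)), with
    sample (n-1) variances.  Requires k >= 2 items, >= 3 rows and positive
    total-score variance.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InsufficientDataError("alpha needs a 2-D matrix with >= 2 items")
    if X.shape[0] < MIN_ROWS_FOR_ALPHA:
        raise InsufficientDataError(
            f"alpha needs >= {MIN_ROWS_FOR_ALPHA} rows, got {X.shape[0]}"
        )
    if np.isnan(X).any():
        raise InsufficientDataError("alpha matrix contains missing cells")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateSampleError("zero total-score variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def segment_matrix(strokes: pd.DataFrame, segment_class: str) -> pd.DataFrame:
    """Participants x ordered-segments matrix of peak vertical velocity.

    Column j holds each participant's (j+1)-th valid segment of the class in
    acquisition order; participants with fewer segments have NaN tails.
    """
    if segment_class not in SEGMENT_CLASSES:
        raise InsufficientDataError(f"unknown segment class {segment_class!r}")
    sub = analysis_strokes(strokes)
    sub = sub[sub["label"] == segment_class].sort_values(
        ["participant_id", "trial", "stroke_index"], kind="stable"
    )
    if sub.empty:
        raise InsufficientDataError(f"no segments of class {segment_class}")
    sub = sub.assign(
        seq=sub.groupby("participant_id").cumcount()
    )
    return sub.pivot(index="participant_id", columns="seq", values="peak_velocity_cm_s")


def incremental_alpha(
    matrix: pd.DataFrame,
    step: int = DEFAULT_STEP,
    max_segments: int = DEFAULT_MAX_SEGMENTS,
) -> pd.DataFrame:
    """Reliability curve: alpha at k = step, 2*step, ..., max_segments.

    Returns a frame with columns ``k``, ``alpha`` and ``n`` (participants
    retained at that width).  Widths with fewer than 3 eligible rows are
    skipped; if no width is computable an error is raised.
    """
    values = matrix.to_numpy(float)
    rows = []
    for k in range(step, max_segments + 1, step):
        if k > values.shape[1]:
            break
        block = values[:, :k]
        keep = ~np.isnan(block).any(axis=1)
        if keep.sum() < MIN_ROWS_FOR_ALPHA:
            log.info("alpha at k=%d skipped: only %d rows", k, int(keep.sum()))
            continue
        rows.append(
            {"k": k, "alpha": cronbach_alpha(block[keep]), "n": int(keep.sum())}
        )
    if not rows:
        raise InsufficientDataError(
            "no segment count had >= 3 participants with complete data"
        )
    return pd.DataFrame(rows)


def reliability_curves(
    strokes: pd.DataFrame,
    classes: tuple[str, ...] = SEGMENT_CLASSES,
    step: int = DEFAULT_STEP,
    max_segments: int = DEFAULT_MAX_SEGMENTS,
) -> pd.DataFrame:
    """Incremental alpha per segment class, long format."""
    frames = []
    for cls in classes:
        curve = incremental_alpha(
            segment_matrix(strokes, cls), step=step, max_segments=max_segments
        )
        curve.insert(0, "segment_class", cls)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def _condition_streams(
    strokes: pd.DataFrame, design: str
) -> dict[str, dict[float, pd.DataFrame]]:
    """Per participant, the chronological segment stream of each dummy level."""
    levels = DESIGN_LEVELS[design]
    sub = analysis_strokes(strokes)
    sub = sub[sub["label"].isin(levels)].sort_values(
        ["participant_id", "trial", "stroke_index"], kind="stable"
    )
    streams: dict[str, dict[float, pd.DataFrame]] = {}
    for (pid, label), grp in sub.groupby(["participant_id", "label"], sort=True):
        streams.setdefault(pid, {})[levels[label]] = grp
    return streams


def slope_stability(
    strokes: pd.DataFrame,
    design: str = "LL",
    step: int = DEFAULT_STEP,
    max_segments: int = DEFAULT_MAX_SEGMENTS,
) -> pd.DataFrame:
    """Stability curve of the VS slope vs segments per condition.

    For each k in {step, 2*step, ..., max_segments} the VS regression is
    refit using only each participant's first k segments of each condition.
    Returns per-k across-participant ``mean_slope``, ``sd_slope``, retained
    ``n`` and ``mean_abs_change`` (mean |slope_k - slope_{k-step}| over
    participants present at both widths).
    """
    streams = _condition_streams(strokes, design)
    per_k: dict[int, dict[str, float]] = {}
    ks = list(range(step, max_segments + 1, step))
    for k in ks:
        slopes = {}
        for pid, levels in streams.items():
            if set(levels) != {0.0, 1.0}:
                continue
            lo, hi = levels[0.0].head(k), levels[1.0].head(k)
            if len(lo) < k or len(hi) < k:
                continue
            both = pd.concat([lo, hi])
            dummy = np.concatenate([np.zeros(len(lo)), np.ones(len(hi))])
            try:
                res = compute_vs(
                    both["peak_velocity_cm_s"].to_numpy(),
                    dummy,
                    both["size_cm"].to_numpy(),
                    participant_id=pid,
                    design=design,
                )
            except (MissingConditionError, CollinearityError) as err:
                log.info("stability k=%d: %s skipped (%s)", k, pid, err)
                continue
            slopes[pid] = res.slope
        if len(slopes) >= 2:
            per_k[k] = slopes
        else:
            log.info("stability k=%d skipped: %d participants", k, len(slopes))
    if not per_k:
        raise InsufficientDataError("no segment count supported a stability point")

    rows = []
    prev: dict[str, float] | None = None
    for k in ks:
        if k not in per_k:
            continue
        slopes = per_k[k]
        vals = np.array(list(slopes.values()))
        if prev is not None:
            common = [p for p in slopes if p in prev]
            change = (
                float(np.mean([abs(slopes[p] - prev[p]) for p in common]))
                if common
                else np.nan
            )
        else:
            change = np.nan
        rows.append(
            {
                "k": k,
                "mean_slope": float(vals.mean()),
                "sd_slope": float(vals.std(ddof=1)),
                "n": len(slopes),
                "mean_abs_change": change,
            }
        )
        prev = slopes
    return pd.DataFrame(rows)


def spearman_brown(rho_single: float, k: int) -> float:
    """Predicted reliability of a k-item parallel test from one item's rho."""
    return k * rho_single / (1.0 + (k - 1) * rho_single)
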