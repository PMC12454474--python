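"""Stroke-level kinematics: filtering, differentiation and segmentation.

Raw pen trajectories (time, x, y, pen-down) are low-pass filtered, vertical
velocity is obtained by central differences, and the trace is cut into
vertical *strokes* at zero crossings of the vertical velocity.  Each stroke
carries the two target variables of the velocity-scaling analysis:

* **Peak Vertical Velocity** — maximum absolute vertical velocity within the
  stroke (direction-free, so up and down strokes pool into one analysis);
* **Vertical Size** — absolute net vertical displacement of the stroke.

A trial is *valid* when it yields at least ``min_segments`` strokes (default
10) and contains no pen-up sample.  For the mixed large/small condition
(``LLee``) strokes are split into the large ("LL") and small ("ee") classes
by an exact 1-D two-means clustering on vertical size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigError, FormatError, TooShortError

CONDITIONS = ("LL1", "LL4", "LLee")

#: Segment classes used downstream: the two separate-loop conditions and the
#: two size classes of the mixed condition.
SEGMENT_CLASSES = ("LL1", "LL4", "ee", "LL")

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_FILTER_ORDER = 2
DEFAULT_MIN_STROKE_SIZE = 0.1  # cm
DEFAULT_MIN_SEGMENTS = 10
#: Ratio of large/small cluster centres below which LLee labelling is flagged
#: as ambiguous.
LLEE_AMBIGUITY_RATIO = 1.5


@dataclass
class PenTrajectory:
    """One trial of raw pen data sampled at a (nearly) uniform rate.

    ``t`` is in seconds and strictly increasing, ``x``/``y`` in cm with y
    increasing upward, ``pen_down`` is 1 while the pen touches the tablet.
    """

    participant_id: str
    condition: str
    trial: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pen_down: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pen_down = np.asarray(self.pen_down, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def validate(self) -> None:
        """Raise :class:`FormatError` if the trajectory invariants fail."""
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r}")
        n = self.n_samples
        if not (self.x.size == n and self.y.size == n and self.pen_down.size == n):
            raise FormatError("t, x, y, pen_down must have equal length")
        if n < 2:
            raise FormatError("trajectory needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise FormatError("time must be strictly increasing")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > 0.1 * med):
            raise FormatError("sampling interval not uniform within 10%")
        if self.t[-1] - self.t[0] < 1.0:
            raise FormatError("trajectory shorter than 1 s")


@dataclass(frozen=True)
class Stroke:
    """One monotone vertical excursion between velocity zero crossings.

    ``start_idx``/``end_idx`` index the trial's sample arrays half-open.
    """

    index: int
    direction: str  # "up" | "down"
    start_idx: int
    end_idx: int
    vertical_size: float  # cm, |y[end-1] - y[start]|
    peak_vertical_velocity: float  # cm/s, max |v_y|
    duration: float  # s


@dataclass
class TrialStrokeSet:
    """Segmentation result for one trial, with the validity flag."""

    participant_id: str
    condition: str
    trial: int
    strokes: list[Stroke]
    valid: bool
    llee_labels: list[str] | None = None
    llee_ambiguous: bool = False
    meta: dict = field(default_factory=dict)


def preprocess(
    traj: PenTrajectory,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass filter y (zero-phase Butterworth) and differentiate.

    Returns ``(y_filtered, v_y)`` with ``v_y`` in cm/s computed by central
    differences (one-sided at the endpoints).

    Raises
    ------
    TooShortError
        If the trajectory is shorter than the filter's padding requirement.
    FormatError
        If the trajectory invariants fail.
    ConfigError
        If the cutoff is at or above the Nyquist frequency.
    """
    traj.validate()
    fs = traj.sampling_rate
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    if cutoff >= fs / 2:
        raise ConfigError(
            f"cutoff {cutoff} Hz not below Nyquist ({fs / 2:.1f} Hz)"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))  # filtfilt's default edge padding
    if traj.n_samples <= padlen:
        raise TooShortError(
            f"{traj.n_samples} samples < padding requirement {padlen + 1} "
            f"for an order-{order} zero-phase filter"
        )
    y_f = signal.filtfilt(b, a, traj.y)
    v_y = np.gradient(y_f, traj.t)
    return y_f, v_y


def _zero_crossing_boundaries(v_y: np.ndarray) -> list[int]:
    """Indices where the sign of v_y flips; zero runs break at their midpoint."""
    s = np.sign(v_y)
    nz = np.flatnonzero(s != 0)
    boundaries: list[int] = []
    for i, j in zip(nz[:-1], nz[1:]):
        if s[i] != s[j]:
            # midpoint of the (possibly empty) zero run between i and j
            boundaries.append(int((i + j + 1) // 2))
    return boundaries


def segment_strokes(
    v_y: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    min_stroke_size: float = DEFAULT_MIN_STROKE_SIZE,
) -> list[Stroke]:
    """Cut a trial into strokes at vertical-velocity zero crossings.

    Candidate segments whose vertical size falls below ``min_stroke_size``
    are merged into the *following* segment (a trailing undersized remainder
    merges backwards), which absorbs jitter reversals without changing the
    count of genuine strokes.  If v_y never changes sign the whole trial is
    returned as a single stroke with a warning.
    """
    v_y = np.asarray(v_y, float)
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    n = v_y.size
    boundaries = _zero_crossing_boundaries(v_y)
    if not boundaries:
        warnings.warn("no vertical-velocity sign change; single-stroke trial")
    edges = [0, *boundaries, n]

    # merge undersized candidates forward, trailing remainder backwards
    spans: list[tuple[int, int]] = []
    carry_start: int | None = None
    for a, b in zip(edges[:-1], edges[1:]):
        start = a if carry_start is None else carry_start
        if abs(y[b - 1] - y[start]) < min_stroke_size:
            carry_start = start
            continue
        spans.append((start, b))
        carry_start = None
    if carry_start is not None:
        if spans:
            last_start, _ = spans.pop()
            spans.append((last_start, n))
        else:
            spans.append((carry_start, n))

    # coalesce adjacent spans with the same excursion direction: an absorbed
    # jitter reversal must not split one monotone excursion into two strokes
    merged: list[tuple[int, int]] = []
    for a, b in spans:
        if merged:
            pa, pb = merged[-1]
            if np.sign(y[b - 1] - y[a]) == np.sign(y[pb - 1] - y[pa]):
                merged[-1] = (pa, b)
                continue
        merged.append((a, b))
    spans = merged

    strokes = []
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    for k, (a, b) in enumerate(spans):
        net = y[b - 1] - y[a]
        seg_v = v_y[a:b]
        direction = "up" if (net > 0 or (net == 0 and seg_v.mean() > 0)) else "down"
        # half-open span: the stroke owns [t[a], t[b]), i.e. b - a sample periods
        end_t = t[b] if b < t.size else t[-1] + dt
        strokes.append(
            Stroke(
                index=k,
                direction=direction,
                start_idx=a,
                end_idx=b,
                vertical_size=abs(net),
                peak_vertical_velocity=float(np.max(np.abs(seg_v))),
                duration=float(end_t - t[a]),
            )
        )
    return strokes


def validate_trial(
    strokes: list[Stroke],
    min_segments: int = DEFAULT_MIN_SEGMENTS,
    pen_up_present: bool = False,
) -> bool:
    """A trial is valid with >= ``min_segments`` strokes and no pen lift."""
    return len(strokes) >= min_segments and not pen_up_present


def _best_1d_split(sorted_sizes: np.ndarray) -> int:
    """Optimal two-cluster split index of sorted values (minimum within-SS).

    Returns p such that clusters are ``sorted_sizes[:p]`` / ``sorted_sizes[p:]``.
    Exhaustive over the n-1 split points, hence exact and deterministic.
    """
    n = sorted_sizes.size
    best_p, best_ss = 1, np.inf
    for p in range(1, n):
        lo, hi = sorted_sizes[:p], sorted_sizes[p:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss:
            best_ss, best_p = ss, p
    return best_p


def label_llee(strokes: list[Stroke]) -> tuple[list[str], bool]:
    """Split LLee strokes into large ("LL") and small ("ee") size classes.

    Uses the exact 1-D two-means split on vertical size; the midpoint of the
    two cluster centres is the labelling threshold and the larger-size
    cluster is "LL".  Returns ``(labels, ambiguous)`` where ``ambiguous`` is
    True (with a warning) when the centre ratio is below
    :data:`LLEE_AMBIGUITY_RATIO`.
    """
    sizes = np.array([s.vertical_size for s in strokes], float)
    if sizes.size < 2:
        warnings.warn("LLee trial with < 2 strokes cannot be split; flagged")
        return ["LL"] * sizes.size, True
    order = np.argsort(sizes, kind="stable")
    p = _best_1d_split(sizes[order])
    c_small = sizes[order][:p].mean()
    c_large = sizes[order][p:].mean()
    ambiguous = False
    if c_small <= 0 or c_large / max(c_small, 1e-12) < LLEE_AMBIGUITY_RATIO:
        warnings.warn(
            f"LLee size clusters not clearly bimodal "
            f"(centres {c_small:.3g}/{c_large:.3g}); trial flagged"
        )
        ambiguous = True
    threshold = 0.5 * (c_small + c_large)
    labels = ["LL" if s >= threshold else "ee" for s in sizes]
    return labels, ambiguous


def process_trial(
    traj: PenTrajectory,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    min_stroke_size: float = DEFAULT_MIN_STROKE_SIZE,
    min_segments: int = DEFAULT_MIN_SEGMENTS,
) -> TrialStrokeSet:
    """Filter, segment and validate one trial; label LLee trials."""
    y_f, v_y = preprocess(traj, cutoff=cutoff, order=order)
    strokes = segment_strokes(v_y, y_f, traj.t, min_stroke_size=min_stroke_size)
    pen_up = bool(np.any(traj.pen_down == 0))
    valid = validate_trial(strokes, min_segments=min_segments, pen_up_present=pen_up)
    labels: list[str] | None = None
    ambiguous = False
    if traj.condition == "LLee" and valid:
        labels, ambiguous = label_llee(strokes)
    return TrialStrokeSet(
        participant_id=traj.participant_id,
        condition=traj.condition,
        trial=traj.trial,
        strokes=strokes,
        valid=valid,
        llee_labels=labels,
        llee_ambiguous=ambiguous,
        meta={"pen_up": pen_up},
    )


def strokes_to_frame(sets: list[TrialStrokeSet]) -> pd.DataFrame:
    """Flatten trial stroke sets into the long stroke table.

    The ``label`` column is the segment class: the condition itself for LL1
    and LL4, and "LL"/"ee" for LLee strokes of unambiguous valid trials.
    """
    rows = []
    for ts in sets:
        for s in ts.strokes:
            if ts.condition == "LLee":
                label = ts.llee_labels[s.index] if ts.llee_labels else ""
            else:
                label = ts.condition
            rows.append(
                {
                    "participant_id": ts.participant_id,
                    "condition": ts.condition,
                    "trial": ts.trial,
                    "stroke_index": s.index,
                    "direction": s.direction,
                    "size_cm": s.vertical_size,
                    "peak_velocity_cm_s": s.peak_vertical_velocity,
                    "duration_s": s.duration,
                    "label": label,
                    "trial_valid": ts.valid,
                    "llee_ambiguous": ts.llee_ambiguous,
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise FormatError("no strokes produced from input trajectories")
    return frame


def process_trajectories(trajs, **kwargs) -> pd.DataFrame:
    """Run :func:`process_trial` over an iterable of trajectories."""
    return strokes_to_frame([process_trial(tr, **kwargs) for tr in trajs])


def analysis_strokes(strokes: pd.DataFrame) -> pd.DataFrame:
    """Strokes eligible for analysis: valid trials, unambiguous LLee labels."""
    keep = strokes["trial_valid"]
    keep &= ~((strokes["condition"] == "LLee") & strokes["llee_ambiguous"])
    return strokes.loc[keep]


def exclusion_filter(
    strokes: pd.DataFrame, min_total: int = DEFAULT_MIN_SEGMENTS
) -> set[str]:
    """Participants retained for LLee analyses.

    A participant is kept when their total count of valid, unambiguously
    labelled segments reaches ``min_total`` in *each* of the "LL" and "ee"
    classes.  Dropped participants remain in the LL1/LL4 analyses.
    """
    llee = analysis_strokes(strokes)
    llee = llee[llee["condition"] == "LLee"]
    counts = (
        llee.groupby(["participant_id", "label"]).size().unstack(fill_value=0)
    )
    for cls in ("LL", "ee"):
        if cls not in counts.columns:
            counts[cls] = 0
    ok = (counts["LL"] >= min_total) & (counts["ee"] >= min_total)
    return set(counts.index[ok])
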