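"""Group and dimensional association models for velocity and VS.

Two families of ordinary least-squares models:

* **Group models** — the outcome regressed on clinical-group dummies with
  healthy controls (HC) as the reference; the overall F test against the
  intercept-only model is reported.  ``three_level`` keeps HC / rMDD / cMDD
  apart; ``lifetime`` collapses remitted and current depression into one
  lifetime-MDD group.
* **Dimensional models** — outcome and predictor(s) standardized to mean 0 /
  SD 1 before the fit, so coefficients are standardized betas with two-sided
  p-values from the coefficient t statistics.  The joint model enters
  anhedonia and general depression together to test unique contributions.

``run_battery`` executes the full registry of 20 models (8 group tests, 10
single-predictor tests, 2 joint models) over both designs; see
:data:`MODEL_REGISTRY`.  p-values are reported uncorrected for multiple
testing, and each model uses listwise deletion of participants missing any
of its variables (dropped counts are logged and recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearityError, ConfigError, DegenerateSampleError
from .synthetic import GROUPS

log = logging.getLogger(__name__)

GROUP_CODINGS = ("three_level", "lifetime")


@dataclass
class AssociationResult:
    """One fitted model: overall F (group models) and/or standardized betas."""

    label: str
    design: str
    outcome: str
    kind: str  # "group" | "dimensional" | "joint"
    n: int
    F: float = np.nan
    df1: int = 0
    df2: int = 0
    p: float = np.nan
    betas: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "model": self.label,
            "design": self.design,
            "outcome": self.outcome,
            "kind": self.kind,
            "n": self.n,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_F": self.p,
            "p_correction": "none",
        }
        for name, (beta, p) in self.betas.items():
            row[f"beta_{name}"] = beta
            row[f"p_{name}"] = p
        return row


def _standardize(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateSampleError(f"{what} has zero variance")
    return (v - v.mean()) / sd


def fit_group_model(
    outcome: np.ndarray,
    groups: np.ndarray,
    coding: str = "three_level",
    label: str = "group",
    design: str = "",
    outcome_name: str = "",
) -> AssociationResult:
    """OLS on group dummies (HC reference) with the overall F test.

    ``lifetime`` coding collapses rMDD and cMDD into a single MDD level.
    Raises :class:`ConfigError` when a required group level is absent.
    """
    outcome = np.asarray(outcome, float)
    groups = np.asarray(groups, object)
    if coding not in GROUP_CODINGS:
        raise ConfigError(f"unknown coding {coding!r}")
    if coding == "lifetime":
        groups = np.where(groups == "HC", "HC", "MDD")
        levels = ("HC", "MDD")
    else:
        levels = GROUPS
    present = set(groups)
    missing = [g for g in levels if g not in present]
    if missing:
        raise ConfigError(f"group level(s) {missing} empty; cannot dummy-code")
    if outcome.size <= len(levels):
        raise DegenerateSampleError("n must exceed the number of predictors + 1")
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X = np.column_stack([np.ones_like(outcome), dummies])
    df1 = len(levels) - 1
    df2 = outcome.size - len(levels)
    # overall F against the intercept-only model, from the RSS reduction
    rss0 = float(np.sum((outcome - outcome.mean()) ** 2))
    beta, _, _, _ = np.linalg.lstsq(X, outcome, rcond=None)
    rss1 = float(np.sum((outcome - X @ beta) ** 2))
    num = max(rss0 - rss1, 0.0) / df1
    den = rss1 / df2
    if num == 0.0:
        F, p = 0.0, 1.0
    elif den == 0.0:
        F, p = np.inf, 0.0
    else:
        F = num / den
        p = float(stats.f.sf(F, df1, df2))
    return AssociationResult(
        label=label,
        design=design,
        outcome=outcome_name,
        kind="group",
        n=int(outcome.size),
        F=float(F),
        df1=df1,
        df2=df2,
        p=p,
    )


def fit_dimensional_model(
    outcome: np.ndarray,
    predictors: pd.DataFrame,
    label: str = "dimensional",
    design: str = "",
    outcome_name: str = "",
) -> AssociationResult:
    """Standardized-beta OLS of an outcome on one or two score columns."""
    outcome = np.asarray(outcome, float)
    if outcome.size <= predictors.shape[1] + 1:
        raise DegenerateSampleError("n must exceed the number of predictors + 1")
    y = _standardize(outcome, outcome_name or "outcome")
    cols = list(predictors.columns)
    Z = np.column_stack(
        [_standardize(predictors[c].to_numpy(float), c) for c in cols]
    )
    if Z.shape[1] > 1:
        r = np.corrcoef(Z, rowvar=False)
        if abs(np.linalg.det(r)) < 1e-12:
            raise CollinearityError(
                f"predictors {cols} are perfectly collinear"
            )
    fit = sm.OLS(y, sm.add_constant(Z)).fit()
    betas = {
        c: (float(fit.params[i + 1]), float(fit.pvalues[i + 1]))
        for i, c in enumerate(cols)
    }
    return AssociationResult(
        label=label,
        design=design,
        outcome=outcome_name,
        kind="joint" if len(cols) > 1 else "dimensional",
        n=int(outcome.size),
        F=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p=float(fit.f_pvalue),
        betas=betas,
    )


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

#: Outcomes per design: the small- and large-condition mean Peak Vertical
#: Velocity and the VS slope.
DESIGN_OUTCOMES = {
    "LL": {"velocity_small": "LL1", "velocity_large": "LL4", "vs": None},
    "LLee": {"velocity_small": "ee", "velocity_large": "LL", "vs": None},
}

#: The battery: 20 models — per design the 3-level group test on the two
#: velocity outcomes and VS plus the lifetime group test on VS (8 group
#: tests); anhedonia on the two velocities and VS plus general depression on
#: VS per design, and general depression on the two LL velocities (10
#: single-predictor tests); the two-predictor joint model on VS per design
#: (2 joint models).  Entries: (label, design, outcome, kind, detail).
MODEL_REGISTRY: list[tuple[str, str, str, str, object]] = []
for _design in ("LL", "LLee"):
    for _out in ("velocity_small", "velocity_large", "vs"):
        MODEL_REGISTRY.append(
            (f"{_design}_{_out}_group3", _design, _out, "group", "three_level")
        )
    MODEL_REGISTRY.append(
        (f"{_design}_vs_group_lifetime", _design, "vs", "group", "lifetime")
    )
    for _out in ("velocity_small", "velocity_large", "vs"):
        MODEL_REGISTRY.append(
            (f"{_design}_{_out}_anhedonia", _design, _out, "dimensional", ["anhedonia"])
        )
    MODEL_REGISTRY.append(
        (
            f"{_design}_vs_general_depression",
            _design,
            "vs",
            "dimensional",
            ["general_depression"],
        )
    )
for _out in ("velocity_small", "velocity_large"):
    MODEL_REGISTRY.append(
        (
            f"LL_{_out}_general_depression",
            "LL",
            _out,
            "dimensional",
            ["general_depression"],
        )
    )
for _design in ("LL", "LLee"):
    MODEL_REGISTRY.append(
        (
            f"{_design}_vs_joint",
            _design,
            "vs",
            "joint",
            ["anhedonia", "general_depression"],
        )
    )
del _design, _out

N_BATTERY_MODELS = len(MODEL_REGISTRY)
assert N_BATTERY_MODELS == 20


def _participant_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Derive the analysis scores from a raw score table if needed.

    Anhedonia is the well-being total reverse-coded (multiplied by -1).
    """
    rec = records.copy()
    if "anhedonia" not in rec.columns:
        rec["anhedonia"] = -rec["wellbeing_total"].astype(float)
    if "general_depression" not in rec.columns:
        rec["general_depression"] = rec["general_depression_total"].astype(float)
    return rec


def _outcome_frame(
    vs: pd.DataFrame, velocity: pd.DataFrame, design: str, outcome: str
) -> pd.DataFrame:
    if outcome == "vs":
        sub = vs[vs["design"] == design]
        return sub[["participant_id", "slope"]].rename(columns={"slope": "y"})
    cls = DESIGN_OUTCOMES[design][outcome]
    sub = velocity[velocity["segment_class"] == cls]
    return sub[["participant_id", "mean_peak_velocity_cm_s"]].rename(
        columns={"mean_peak_velocity_cm_s": "y"}
    )


def run_battery(
    vs: pd.DataFrame, velocity: pd.DataFrame, records: pd.DataFrame
) -> pd.DataFrame:
    """Fit every registry model and return one row per model (20 rows).

    Inputs are joined on ``participant_id``; participants missing any
    variable of a given model are dropped for that model only, with the
    dropped count logged and recorded in the ``n_dropped`` column.
    """
    rec = _participant_scores(records)
    n_known = rec["participant_id"].nunique()
    if n_known == 0:
        raise ConfigError("empty participant record table")
    rows = []
    for label, design, outcome, kind, detail in MODEL_REGISTRY:
        yframe = _outcome_frame(vs, velocity, design, outcome)
        merged = yframe.merge(rec, on="participant_id", how="inner")
        if kind == "group":
            cols = ["y", "group"]
        else:
            cols = ["y", *detail]
        merged = merged.dropna(subset=cols)
        if merged.empty:
            raise ConfigError(f"model {label}: no participants after the join")
        n_dropped = n_known - len(merged)
        if n_dropped:
            log.info("model %s: %d participants dropped listwise", label, n_dropped)
        if kind == "group":
            res = fit_group_model(
                merged["y"].to_numpy(),
                merged["group"].to_numpy(),
                coding=detail,
                label=label,
                design=design,
                outcome_name=outcome,
            )
        else:
            res = fit_dimensional_model(
                merged["y"].to_numpy(),
                merged[detail],
                label=label,
                design=design,
                outcome_name=outcome,
            )
        row = res.to_row()
        row["n_dropped"] = n_dropped
        rows.append(row)
    return pd.DataFrame(rows)
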