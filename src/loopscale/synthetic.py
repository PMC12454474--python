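"""Seeded synthetic cohort generator for the loop-writing task.

The generator emulates a pen-tablet loop-writing protocol: three task
conditions (continuous loops in a 1 cm boundary, in a 4 cm boundary, and
alternating pairs of large/small cursive loops), three trials per condition,
eight loops (= sixteen vertical strokes) per trial, and a clinical cohort of
healthy controls (HC), remitted (rMDD) and current (cMDD) depression groups
with dimensional anhedonia and general-depression scores.

Generative kinematic model
--------------------------
Each stroke's vertical velocity is a half sine with peak ``v_p``; for
amplitude ``A`` the stroke duration is the closed form ``d = pi*A/(2*v_p)``,
which makes amplitude, peak velocity and duration exactly consistent and
gives the test suite analytic oracles.  A subject plans peak velocity from
the condition's *target* amplitude,

    v_p = baseline_velocity + scaling_gain * (target - 1 cm) + noise,

while the realized stroke amplitude varies around the target.  The subject's
``scaling_gain`` (cm/s per cm) is therefore the quantity the downstream
velocity-scaling slope estimates (times the 3 cm condition step), and the
within-condition amplitude variability is what makes the size covariate
identifiable alongside the condition dummy.

Scores are drawn from per-group bivariate normals (anhedonia is the
well-being scale reverse-coded); the within-group residual correlation is
solved so that the *pooled* anhedonia x general-depression correlation hits
the configured target.  Each subject's scaling gain is coupled to their
population-standardized anhedonia with standardized slope
``anhedonia_vs_effect``, enabling exact parameter-recovery tests via the
returned truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidSpecError
from .kinematics import PenTrajectory

GROUPS = ("HC", "rMDD", "cMDD")

#: Condition target amplitudes, cm.  LLee alternates pairs of large and small
#: loops (cursive "LLeeLLee"), i.e. per 8-loop trial: 2 large, 2 small, 2
#: large, 2 small loops.
CONDITION_TARGETS = {"LL1": 1.0, "LL4": 4.0}
LLEE_LARGE, LLEE_SMALL = 4.0, 1.0

PEAK_VELOCITY_FLOOR = 0.05  # cm/s, guards degenerate negative draws
AMPLITUDE_FLOOR = 0.05  # cm


@dataclass(frozen=True)
class StrokeSpec:
    """Planned stroke: amplitude (cm), peak velocity (cm/s) and direction."""

    amplitude: float
    peak_velocity: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise InvalidSpecError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.peak_velocity > 0:
            raise InvalidSpecError(
                f"peak_velocity must be > 0, got {self.peak_velocity}"
            )
        if self.direction not in ("up", "down"):
            raise InvalidSpecError(f"direction must be up/down, got {self.direction}")

    @property
    def duration(self) -> float:
        """Closed-form stroke duration d = pi*A/(2*v_p), seconds."""
        return math.pi * self.amplitude / (2.0 * self.peak_velocity)


@dataclass(frozen=True)
class SubjectKinematics:
    """Per-subject generative kinematic parameters.

    ``baseline_velocity`` is the expected peak velocity of a 1 cm stroke;
    ``scaling_gain`` the true increase in peak velocity per cm of target
    amplitude; ``amplitude_sd`` the within-condition size SD *per cm of
    target* (so a 4 cm target gets four times the absolute SD of a 1 cm
    target); ``velocity_noise_sd`` the per-stroke peak-velocity noise.
    """

    baseline_velocity: float
    scaling_gain: float
    amplitude_sd: float = 0.12
    velocity_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.baseline_velocity > 0:
            raise InvalidSpecError("baseline_velocity must be > 0")
        if not self.amplitude_sd > 0:
            raise InvalidSpecError(
                "amplitude_sd must be > 0 (required so the size covariate is "
                "identifiable next to the condition dummy)"
            )
        if self.velocity_noise_sd < 0:
            raise InvalidSpecError("velocity_noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, score structure and task geometry.

    Score means/SDs default to the clinical ordering cMDD > rMDD > HC on
    general depression (and the reverse on well-being).
    ``depression_anhedonia_corr`` is the target correlation *pooled across
    groups*; ``anhedonia_vs_effect`` the true standardized slope of the
    subject scaling gain on anhedonia.
    """

    n_hc: int = 85
    n_rmdd: int = 97
    n_cmdd: int = 49
    anhedonia_vs_effect: float = -0.16
    depression_anhedonia_corr: float = 0.55
    group_depression_means: tuple[float, float, float] = (24.6, 32.1, 52.5)
    group_depression_sds: tuple[float, float, float] = (7.2, 9.4, 11.4)
    group_wellbeing_means: tuple[float, float, float] = (24.2, 22.5, 16.6)
    group_wellbeing_sds: tuple[float, float, float] = (6.7, 6.7, 5.9)
    #: additive per-group shifts on the scaling-gain mean (HC, rMDD, cMDD);
    #: zero by default (no group kinematic effect), configurable for power
    #: studies.
    group_gain_shifts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gain_mean: float = 1.67
    gain_sd: float = 0.25
    baseline_mean: float = 1.7
    baseline_sd: float = 0.3
    velocity_noise_sd: float = 0.1
    amplitude_sd: float = 0.12
    sampling_rate: float = 100.0
    loops_per_trial: int = 8
    trials_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_rmdd, self.n_cmdd) < 1:
            raise ConfigError("all group counts must be >= 1")
        if not abs(self.depression_anhedonia_corr) < 1:
            raise ConfigError("|depression_anhedonia_corr| must be < 1")
        if not abs(self.anhedonia_vs_effect) <= 1:
            raise ConfigError("|anhedonia_vs_effect| must be <= 1")
        if self.sampling_rate < 50:
            raise ConfigError("sampling_rate must be >= 50 Hz")
        if self.loops_per_trial < 1 or self.trials_per_condition < 1:
            raise ConfigError("loops and trials must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_hc + self.n_rmdd + self.n_cmdd

    @property
    def group_sizes(self) -> tuple[int, int, int]:
        return (self.n_hc, self.n_rmdd, self.n_cmdd)


# ---------------------------------------------------------------------------
# score model
# ---------------------------------------------------------------------------

def _pooled_moments(weights, means, sds):
    mu = float(np.dot(weights, means))
    var = float(np.dot(weights, np.square(sds)) + np.dot(weights, (np.asarray(means) - mu) ** 2))
    return mu, var


def residual_score_correlation(config: CohortConfig) -> float:
    """Within-group residual correlation implied by the pooled target.

    The pooled covariance splits into a between-group part (from the group
    mean shifts) and a within-group part ``rho * sum_g w_g sd_dg sd_ag``;
    solving for ``rho`` hits the configured pooled correlation exactly in
    the population.  Raises :class:`ConfigError` when the implied residual
    correlation is infeasible (the implied covariance matrix would not be
    positive definite).
    """
    w = np.array(config.group_sizes, float) / config.n_total
    anh_means = -np.asarray(config.group_wellbeing_means)
    anh_sds = np.asarray(config.group_wellbeing_sds)
    dep_means = np.asarray(config.group_depression_means)
    dep_sds = np.asarray(config.group_depression_sds)

    mu_a, var_a = _pooled_moments(w, anh_means, anh_sds)
    mu_d, var_d = _pooled_moments(w, dep_means, dep_sds)
    between_cov = float(np.dot(w, (dep_means - mu_d) * (anh_means - mu_a)))
    target_cov = config.depression_anhedonia_corr * math.sqrt(var_a * var_d)
    within_scale = float(np.dot(w, dep_sds * anh_sds))
    rho = (target_cov - between_cov) / within_scale
    if not abs(rho) < 1:
        raise ConfigError(
            f"implied within-group score correlation {rho:.3f} is infeasible "
            "(implied covariance not positive definite); relax the group "
            "shifts or the pooled correlation target"
        )
    return rho


def anhedonia_population_moments(config: CohortConfig) -> tuple[float, float]:
    """Pooled population mean and SD of the anhedonia score."""
    w = np.array(config.group_sizes, float) / config.n_total
    mu, var = _pooled_moments(
        w, -np.asarray(config.group_wellbeing_means), config.group_wellbeing_sds
    )
    return mu, math.sqrt(var)


def draw_cohort_subjects(
    config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw scores and true kinematic parameters for every participant.

    Returns the truth table: one row per participant with group, scores and
    the generative ``scaling_gain`` / ``baseline_velocity``.
    """
    rho = residual_score_correlation(config)
    mu_a, sd_a = anhedonia_population_moments(config)
    e = config.anhedonia_vs_effect

    rows = []
    idx = 0
    for g, n, dep_mu, dep_sd, wb_mu, wb_sd, gain_shift in zip(
        GROUPS,
        config.group_sizes,
        config.group_depression_means,
        config.group_depression_sds,
        config.group_wellbeing_means,
        config.group_wellbeing_sds,
        config.group_gain_shifts,
    ):
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        dep = dep_mu + dep_sd * z1
        anh = -wb_mu + wb_sd * (rho * z1 + math.sqrt(1 - rho**2) * z2)
        z_anh = (anh - mu_a) / sd_a
        eta = rng.standard_normal(n)
        gain = (
            config.gain_mean
            + gain_shift
            + config.gain_sd * (e * z_anh + math.sqrt(1 - e**2) * eta)
        )
        baseline = np.maximum(
            config.baseline_mean + config.baseline_sd * rng.standard_normal(n), 0.1
        )
        for k in range(n):
            idx += 1
            rows.append(
                {
                    "participant_id": f"P{idx:03d}",
                    "group": g,
                    "anhedonia": anh[k],
                    "general_depression": dep[k],
                    "wellbeing_total": -anh[k],
                    "scaling_gain": gain[k],
                    "baseline_velocity": baseline[k],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinematic simulation
# ---------------------------------------------------------------------------

def simulate_stroke(
    spec: StrokeSpec, rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one half-sine stroke at ``rate`` Hz.

    Returns ``(t, y, v_y)`` with the stroke starting at y = 0.  The velocity
    profile is ``v(t) = s * v_p * sin(pi t / d)`` with
    ``d = pi*A/(2*v_p)``, whose integral gives net displacement exactly
    ``s * A``.
    """
    if rate < 50:
        raise ConfigError("sampling rate must be >= 50 Hz")
    d = spec.duration
    t = np.arange(0.0, d, 1.0 / rate)
    s = 1.0 if spec.direction == "up" else -1.0
    phase = math.pi * t / d
    v = s * spec.peak_velocity * np.sin(phase)
    y = s * spec.amplitude * (1.0 - np.cos(phase)) / 2.0
    return t, y, v


def loop_targets(condition: str, loops: int) -> np.ndarray:
    """Per-loop target amplitude for a condition.

    LLee alternates pairs of loops large, large, small, small, ...
    """
    if condition in CONDITION_TARGETS:
        return np.full(loops, CONDITION_TARGETS[condition])
    if condition == "LLee":
        return np.array(
            [LLEE_LARGE if (i // 2) % 2 == 0 else LLEE_SMALL for i in range(loops)]
        )
    raise ConfigError(f"unknown condition {condition!r}")


def draw_trial_specs(
    subject: SubjectKinematics,
    condition: str,
    loops: int,
    rng: np.random.Generator,
) -> tuple[list[StrokeSpec], np.ndarray]:
    """Draw the 2*loops stroke specs of one trial.

    Returns ``(specs, targets)`` where ``targets`` is the per-stroke target
    amplitude.  Realized amplitudes vary around the target with SD
    ``amplitude_sd * target``; peak velocity is planned from the target, with
    additive noise, floored at :data:`PEAK_VELOCITY_FLOOR`.
    """
    if loops < 1:
        raise ConfigError("loops must be >= 1")
    targets = np.repeat(loop_targets(condition, loops), 2)
    amps = np.maximum(
        targets + rng.normal(0.0, subject.amplitude_sd * targets),
        AMPLITUDE_FLOOR,
    )
    peaks = np.maximum(
        subject.baseline_velocity
        + subject.scaling_gain * (targets - 1.0)
        + rng.normal(0.0, subject.velocity_noise_sd, size=targets.size),
        PEAK_VELOCITY_FLOOR,
    )
    specs = [
        StrokeSpec(a, v, "up" if i % 2 == 0 else "down")
        for i, (a, v) in enumerate(zip(amps, peaks))
    ]
    return specs, targets


def render_trial(
    specs: list[StrokeSpec],
    rate: float,
    participant_id: str = "P000",
    condition: str = "LL1",
    trial: int = 1,
) -> PenTrajectory:
    """Render stroke specs to a uniformly sampled pen trajectory.

    Positions are evaluated analytically on a global uniform time grid, so
    the sampling interval is exactly 1/rate and each stroke occupies
    ``round(rate * d)`` samples up to one-sample discretization.  A smooth
    half-sine horizontal bulge plus a constant drift makes loops loop-like.
    """
    durations = np.array([s.duration for s in specs])
    ends = np.cumsum(durations)
    starts = ends - durations
    y0 = np.concatenate(
        [[0.0], np.cumsum([(1 if s.direction == "up" else -1) * s.amplitude for s in specs])]
    )[:-1]
    total = ends[-1]
    t = np.arange(0.0, total, 1.0 / rate)
    j = np.clip(np.searchsorted(ends, t, side="right"), 0, len(specs) - 1)
    tau = t - starts[j]
    d_j = durations[j]
    amp = np.array([s.amplitude for s in specs])[j]
    sign = np.array([1.0 if s.direction == "up" else -1.0 for s in specs])[j]
    phase = np.pi * tau / d_j
    y = y0[j] + sign * amp * (1.0 - np.cos(phase)) / 2.0
    x = 0.5 * t + 0.25 * amp * np.sin(phase)
    return PenTrajectory(
        participant_id=participant_id,
        condition=condition,
        trial=trial,
        t=t,
        x=x,
        y=y,
        pen_down=np.ones(t.size, dtype=int),
    )


def simulate_trial(
    subject: SubjectKinematics,
    condition: str,
    loops: int,
    rate: float,
    rng: np.random.Generator,
    participant_id: str = "P000",
    trial: int = 1,
) -> PenTrajectory:
    """Draw and render one trial of loop writing."""
    specs, _ = draw_trial_specs(subject, condition, loops, rng)
    return render_trial(specs, rate, participant_id, condition, trial)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PenTrajectory], pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort: trajectories, score table and truth table.

    Fully reproducible from ``config.seed``: the seed fans out through a
    ``SeedSequence`` into one child stream for the subject draw and one per
    participant for the kinematics, so participant k's trajectories do not
    depend on how many participants precede them in the loop.
    """
    ss = np.random.SeedSequence(config.seed)
    subj_ss, kin_ss = ss.spawn(2)
    truth = draw_cohort_subjects(config, np.random.default_rng(subj_ss))

    trajectories: list[PenTrajectory] = []
    child_seeds = kin_ss.spawn(len(truth))
    for (row, child) in zip(truth.itertuples(index=False), child_seeds):
        rng = np.random.default_rng(child)
        subject = SubjectKinematics(
            baseline_velocity=row.baseline_velocity,
            scaling_gain=row.scaling_gain,
            amplitude_sd=config.amplitude_sd,
            velocity_noise_sd=config.velocity_noise_sd,
        )
        for condition in ("LL1", "LL4", "LLee"):
            for trial in range(1, config.trials_per_condition + 1):
                trajectories.append(
                    simulate_trial(
                        subject,
                        condition,
                        config.loops_per_trial,
                        config.sampling_rate,
                        rng,
                        participant_id=row.participant_id,
                        trial=trial,
                    )
                )
    records = truth[
        ["participant_id", "group", "wellbeing_total", "general_depression"]
    ].rename(columns={"general_depression": "general_depression_total"})
    truth_out = truth[
        [
            "participant_id",
            "group",
            "anhedonia",
            "general_depression",
            "scaling_gain",
            "baseline_velocity",
        ]
    ]
    return trajectories, records.copy(), truth_out.copy()


# ---------------------------------------------------------------------------
# stroke-measurement fast path (no time-series rendering)
# ---------------------------------------------------------------------------

def simulate_design_measurements(
    config: CohortConfig,
    design: str,
    rng: np.random.Generator,
    truth: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw per-stroke (size, peak velocity) measurements for one design.

    This is the same per-stroke measurement model as
    :func:`draw_trial_specs`, drawn for every participant at once without
    rendering or re-segmenting time series — the natural tool for
    Monte-Carlo studies of the downstream estimators.

    Returns ``(peaks, sizes, dummy, truth)`` where ``peaks`` and ``sizes``
    are (n_participants, n_segments) arrays in acquisition order, ``dummy``
    the shared condition indicator (LL: 0 = 1 cm, 1 = 4 cm; LLee: 0 = small,
    1 = large), and ``truth`` the subject truth table used.
    """
    if design not in ("LL", "LLee"):
        raise ConfigError(f"unknown design {design!r}")
    if truth is None:
        truth = draw_cohort_subjects(config, rng)
    n = len(truth)
    loops, trials = config.loops_per_trial, config.trials_per_condition

    if design == "LL":
        per_cond = 2 * loops * trials
        targets = np.concatenate(
            [np.full(per_cond, 1.0), np.full(per_cond, 4.0)]
        )
    else:
        targets = np.tile(np.repeat(loop_targets("LLee", loops), 2), trials)
    dummy = (targets == LLEE_LARGE).astype(float)

    gains = truth["scaling_gain"].to_numpy()[:, None]
    bases = truth["baseline_velocity"].to_numpy()[:, None]
    m = targets.size
    sizes = np.maximum(
        targets + rng.normal(0.0, config.amplitude_sd * targets, size=(n, m)),
        AMPLITUDE_FLOOR,
    )
    peaks = np.maximum(
        bases
        + gains * (targets - 1.0)
        + rng.normal(0.0, config.velocity_noise_sd, size=(n, m)),
        PEAK_VELOCITY_FLOOR,
    )
    return peaks, sizes, dummy, truth


def with_overrides(config: CohortConfig, **kwargs) -> CohortConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
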