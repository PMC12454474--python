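import numpy as np
import pandas as pd
import pytest

from loopscale import kinematics as kin
from loopscale import synthetic as syn


def noise_free_specs(amplitude: float, peak: float, loops: int = 8):
    """Alternating up/down stroke specs with identical amplitude and peak."""
    return [
        syn.StrokeSpec(amplitude, peak, "up" if i % 2 == 0 else "down")
        for i in range(2 * loops)
    ]


def noise_free_trial(
    amplitude: float = 4.0,
    peak: float = 6.6,
    loops: int = 8,
    rate: float = 100.0,
    condition: str = "LL4",
    trial: int = 1,
    participant_id: str = "P000",
):
    return syn.render_trial(
        noise_free_specs(amplitude, peak, loops),
        rate,
        participant_id=participant_id,
        condition=condition,
        trial=trial,
    )


def make_stroke_frame(rows):
    """Build a stroke table from (pid, condition, trial, idx, size, peak, label)."""
    frame = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "trial",
            "stroke_index",
            "size_cm",
            "peak_velocity_cm_s",
            "label",
        ],
    )
    frame["direction"] = np.where(frame["stroke_index"] % 2 == 0, "up", "down")
    frame["duration_s"] = 1.0
    frame["trial_valid"] = True
    frame["llee_ambiguous"] = False
    return frame


def measurement_stroke_frame(
    config: syn.CohortConfig,
    rng: np.random.Generator,
    design: str = "LL",
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stroke table for one design from the measurement fast path."""
    peaks, sizes, dummy, truth = syn.simulate_design_measurements(
        config, design, rng, truth=truth
    )
    n, m = peaks.shape
    per_trial = 2 * config.loops_per_trial
    if design == "LL":
        per_cond = m // 2
        labels = np.array(["LL1"] * per_cond + ["LL4"] * per_cond)
        condition = labels
        trials = (np.arange(m) % per_cond) // per_trial + 1
    else:
        labels = np.where(dummy == 1.0, "LL", "ee")
        condition = np.array(["LLee"] * m)
        trials = np.arange(m) // per_trial + 1
    rows = []
    for i, pid_row in enumerate(truth.itertuples(index=False)):
        for j in range(m):
            rows.append(
                (
                    pid_row.participant_id,
                    condition[j],
                    int(trials[j]),
                    j,
                    sizes[i, j],
                    peaks[i, j],
                    labels[j],
                )
            )
    return make_stroke_frame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-participant cohort run through the full trajectory pipeline."""
    cfg = syn.CohortConfig(n_hc=6, n_rmdd=6, n_cmdd=4, seed=7)
    trajs, records, truth = syn.simulate_cohort(cfg)
    strokes = kin.process_trajectories(trajs)
    return {
        "config": cfg,
        "trajectories": trajs,
        "records": records,
        "truth": truth,
        "strokes": strokes,
    }
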