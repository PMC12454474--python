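# loopscale

Kinematic analysis of pen-tablet loop writing for quantifying **psychomotor
retardation (PmR)** — the motor slowing seen in depression — via **velocity
scaling (VS)**: the ability to speed up pen movement in proportion to
movement size. The package is aimed at researchers in psychomotor
kinematics and digital phenotyping who want a tested, reproducible
implementation of the stroke-level VS statistic, its association models and
its psychometrics, exercised end-to-end on a synthetic cohort generator
(raw clinical handwriting data of this kind are typically access-restricted).

## The task and the statistic

Participants write 8 continuous cursive loops per trial, three trials per
condition, under three conditions: loops inside a 1 cm vertical boundary
(`LL1`), inside a 4 cm boundary (`LL4`), and alternating pairs of large and
small loops in one trial (`LLee`, cursive "LLeeLLee"). Each trial is
low-pass filtered (zero-phase Butterworth, 10 Hz), differentiated, and cut
into vertical **strokes** at zero crossings of vertical velocity — 16
strokes (8 up, 8 down) per clean 8-loop trial. A trial is valid with at
least 10 strokes and no pen lift. Each stroke yields its **Peak Vertical
Velocity** `v_p = max |dy/dt|` and **Vertical Size** `S = |Δy|`; LLee
strokes are split into large ("LL") and small ("ee") classes by an exact
1-D two-means clustering on size.

The per-participant VS slope is the condition coefficient `b1` of the
pooled ordinary least-squares fit over all valid segments of a design,

```
v_p = b0 + b1 * condition + b2 * S + e,     condition ∈ {0, 1}
```

with the small condition as reference (LL: 1 cm = 0, 4 cm = 1; LLee:
ee = 0, LL = 1) and size as covariate. Steeper positive slopes mean
stronger velocity scaling, i.e. less psychomotor slowing. Downstream, the
package fits the full association battery (20 models: group F-tests with
3-level and lifetime codings, standardized-beta regressions on anhedonia
and general depression, and the two-predictor joint model) and the
psychometric analyses: segment-incremental Cronbach's alpha curves
(k = 2, 4, …, 48 segments) and VS slope-stability curves.

The synthetic cohort generator produces seeded trajectories with half-sine
stroke velocity profiles (duration `d = πA/(2 v_p)`), a clinical group
structure (85 healthy controls, 97 remitted, 49 current MDD), anhedonia and
general-depression scores with a pooled correlation of .55, and a
configurable true anhedonia→VS coupling (default standardized slope −0.16),
plus a truth table for parameter-recovery testing.

## Worked example

```python
import numpy as np
from loopscale import synthetic as syn, kinematics as kin, scaling as sc
from loopscale import association as assoc, psychometrics as psy

cfg = syn.CohortConfig(n_hc=20, n_rmdd=20, n_cmdd=12, seed=42)
trajs, records, truth = syn.simulate_cohort(cfg)
strokes = kin.process_trajectories(trajs)

retained = kin.exclusion_filter(strokes)          # LLee-eligible participants
vs = sc.vs_table(strokes, llee_participants=retained)
print(vs[vs.design == "LL"].head(3)[
    ["participant_id", "slope", "size_coefficient", "n_segments", "slope_z"]
].to_string(index=False))

merged = vs[vs.design == "LL"].merge(truth, on="participant_id")
print("corr(slope, 3*gain): %.3f"
      % np.corrcoef(merged.slope, 3 * merged.scaling_gain)[0, 1])

battery = assoc.run_battery(vs, sc.mean_peak_velocity(strokes), records)
row = battery[battery.model == "LL_vs_anhedonia"].iloc[0]
print("LL VS ~ anhedonia: beta = %.3f, p = %.3f, n = %d"
      % (row.beta_anhedonia, row.p_anhedonia, row.n))

curves = psy.reliability_curves(strokes)
print(curves[curves.segment_class == "LL1"].head(3).to_string(index=False))
```

prints

```
participant_id    slope  size_coefficient  n_segments   slope_z
          P001 6.210196          0.020482          96  1.757966
          P002 5.272295          0.005217          96  0.301499
          P003 4.071178          0.002440          96 -1.563714
corr(slope, 3*gain): 0.990
LL VS ~ anhedonia: beta = -0.062, p = 0.663, n = 52
segment_class  k    alpha  n
          LL1  2 0.950912 52
          LL1  4 0.973341 52
          LL1  6 0.981643 52
```

Each participant's LL slope is fitted from 96 segments (48 per condition
over three trials); the slope tracks three times the generative per-cm
scaling gain (the 1→4 cm condition step is 3 cm) almost perfectly. At this
demonstration size (n = 52) the anhedonia beta is dominated by sampling
error — recovering the −0.16 coupling reliably takes the full 231-person
cohort (see below). Peak-velocity reliability is excellent already at one
loop (alpha ≈ 0.95 at k = 2) and grows with segment count.

The same stages are available as CLI subcommands:

```sh
loopscale simulate --out sim --seed 1
loopscale process --in sim --out strokes.tsv
loopscale vs --strokes strokes.tsv --out vs.tsv
loopscale associate --vs vs.tsv --strokes strokes.tsv --scores sim/scores.csv --out results.tsv
loopscale reliability --strokes strokes.tsv --out reliability.tsv
loopscale run-all --out run --seed 1      # everything, plus summary.md
```

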