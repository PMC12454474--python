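"""Filtering, differentiation, zero-crossing segmentation, trial validity,
LLee labelling and the LLee exclusion filter."""

import warnings

import numpy as np
import pytest

from loopscale import kinematics as kin
from loopscale import synthetic as syn
from loopscale.exceptions import ConfigError, FormatError, TooShortError

from conftest import make_stroke_frame, noise_free_specs, noise_free_trial


def _traj(t, y, condition="LL1", pen_down=None):
    t = np.asarray(t, float)
    return kin.PenTrajectory(
        participant_id="P001",
        condition=condition,
        trial=1,
        t=t,
        x=np.zeros_like(t),
        y=np.asarray(y, float),
        pen_down=np.ones(t.size, int) if pen_down is None else pen_down,
    )


class TestPreprocess:
    def test_constant_position_zero_velocity(self):
        t = np.arange(0, 2, 0.01)
        _, v = kin.preprocess(_traj(t, np.full(t.size, 3.0)))
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_sine_peak_velocity_analytic(self):
        # y = sin(2*pi*2t): dy/dt peaks at 4*pi cm/s, well below a 10 Hz cutoff
        t = np.arange(0, 10, 0.01)
        _, v = kin.preprocess(_traj(t, np.sin(2 * np.pi * 2 * t)))
        assert np.max(v) == pytest.approx(4 * np.pi, rel=0.03)

    def test_too_short_for_filter_padding(self):
        t = np.arange(10) * 0.2  # 1.8 s, but only 10 samples
        with pytest.raises(TooShortError):
            kin.preprocess(_traj(t, np.sin(t)), cutoff=1.0, order=3)

    def test_nonuniform_timing_rejected(self):
        t = np.array([0, 0.01, 0.025, 0.03, *np.arange(0.04, 1.2, 0.01)])
        with pytest.raises(FormatError):
            kin.preprocess(_traj(t, np.sin(t)))

    def test_cutoff_above_nyquist_rejected(self):
        t = np.arange(0, 2, 0.05)  # 20 Hz sampling
        with pytest.raises(ConfigError):
            kin.preprocess(_traj(t, np.sin(t)), cutoff=10.0)


class TestSegmentation:
    def test_noise_free_trial_yields_16_alternating_strokes(self):
        ts = kin.process_trial(noise_free_trial())
        assert len(ts.strokes) == 16
        assert [s.direction for s in ts.strokes] == ["up", "down"] * 8
        assert ts.valid

    def test_all_positive_velocity_single_stroke(self):
        t = np.arange(0, 2, 0.01)
        y = t.copy()
        with pytest.warns(UserWarning, match="single-stroke"):
            strokes = kin.segment_strokes(np.ones_like(t), y, t)
        assert len(strokes) == 1 and strokes[0].direction == "up"

    def test_jitter_reversal_absorbed(self):
        """A 0.02 cm reversal below min_stroke_size must not change the
        stroke count or move the genuine boundaries."""
        t = np.arange(0, 3, 0.01)
        y_clean = np.where(t < 2, t, 2 - (t - 2) * 2)  # up 2 cm, down 2 cm
        jitter = np.where((t >= 1.0) & (t < 1.1), -0.02 * np.sin(
            np.pi * (t - 1.0) / 0.1) ** 2, 0.0)
        y = y_clean + 2 * jitter
        v = np.gradient(y, t)
        clean = kin.segment_strokes(np.gradient(y_clean, t), y_clean, t)
        noisy = kin.segment_strokes(v, y, t, min_stroke_size=0.1)
        assert len(noisy) == len(clean) == 2
        assert [s.direction for s in noisy] == ["up", "down"]
        # genuine boundary still at the velocity sign change near t = 2
        assert abs(t[noisy[0].end_idx] - 2.0) < 0.05

    def test_partition_and_roundtrip(self):
        tr = noise_free_trial(amplitude=2.0, peak=3.3)
        y_f, v = kin.preprocess(tr)
        strokes = kin.segment_strokes(v, y_f, tr.t)
        # strokes tile the trial with no gaps or overlaps
        assert strokes[0].start_idx == 0
        assert strokes[-1].end_idx == tr.n_samples
        for a, b in zip(strokes[:-1], strokes[1:]):
            assert a.end_idx == b.start_idx
        # summed signed displacements reproduce the net trajectory change
        signed = sum(
            (1 if s.direction == "up" else -1) * s.vertical_size for s in strokes
        )
        assert signed == pytest.approx(y_f[-1] - y_f[0], abs=0.05)

    def test_measured_kinematics_match_generating_specs(self):
        """Filter-attenuation bound: sizes and peak velocities within 3%,
        durations within one sample of the closed form."""
        specs = noise_free_specs(amplitude=4.0, peak=6.6)
        tr = syn.render_trial(specs, 100.0, condition="LL4")
        ts = kin.process_trial(tr)
        assert len(ts.strokes) == 16
        d_expected = specs[0].duration
        for s, spec in zip(ts.strokes, specs):
            assert s.vertical_size == pytest.approx(spec.amplitude, rel=0.03)
            assert s.peak_vertical_velocity == pytest.approx(
                spec.peak_velocity, rel=0.03
            )
            assert abs(s.duration - d_expected) <= 1.0 / 100.0


class TestValidity:
    @pytest.mark.parametrize("n,expected", [(16, True), (10, True), (9, False)])
    def test_segment_count_threshold(self, n, expected):
        ts = kin.process_trial(noise_free_trial(loops=8))
        strokes = ts.strokes[:n]
        assert kin.validate_trial(strokes) is expected

    def test_pen_lift_invalidates_trial(self):
        tr = noise_free_trial()
        tr.pen_down[50:60] = 0
        ts = kin.process_trial(tr)
        assert not ts.valid and ts.meta["pen_up"]


class TestLabelLLee:
    def _strokes_from_sizes(self, sizes):
        return [
            kin.Stroke(i, "up", 0, 1, s, 1.0, 1.0) for i, s in enumerate(sizes)
        ]

    def test_alternating_pairs_pattern(self):
        sizes = [4, 4, 1, 1, 4, 4, 1, 1]
        labels, ambiguous = kin.label_llee(self._strokes_from_sizes(sizes))
        assert labels == ["LL", "LL", "ee", "ee"] * 2
        assert not ambiguous

    def test_equal_sizes_flagged_ambiguous(self):
        with pytest.warns(UserWarning, match="bimodal"):
            _, ambiguous = kin.label_llee(self._strokes_from_sizes([2.0] * 8))
        assert ambiguous

    def test_gaussian_clusters_zero_misassignments(self):
        rng = np.random.default_rng(21)
        small = rng.normal(1, 0.1, 8)
        large = rng.normal(4, 0.4, 8)
        sizes = np.empty(16)
        sizes[0::2], sizes[1::2] = small, large
        labels, ambiguous = kin.label_llee(self._strokes_from_sizes(sizes))
        assert not ambiguous
        assert labels[0::2] == ["ee"] * 8 and labels[1::2] == ["LL"] * 8
        # cross-check the split against the brute-force optimal threshold
        best = min(
            (np.var(sizes[sizes <= th]) * (sizes <= th).sum()
             + np.var(sizes[sizes > th]) * (sizes > th).sum(), th)
            for th in np.sort(sizes)[:-1]
        )[1]
        assert all(
            (lbl == "LL") == (sz > best) for lbl, sz in zip(labels, sizes)
        )


class TestExclusionFilter:
    @staticmethod
    def _cohort_frame(n_participants, deficient=()):
        rows = []
        for i in range(n_participants):
            pid = f"P{i + 1:03d}"
            if pid in deficient:
                continue
            for trial in range(1, 4):
                for j in range(16):
                    label = "LL" if (j // 4) % 2 == 0 else "ee"
                    size = 4.0 + 0.1 * j if label == "LL" else 1.0 + 0.05 * j
                    rows.append(("LLee", pid, trial, j, size, 5.0, label))
        return make_stroke_frame(
            [(p, c, t, j, s, v, l) for c, p, t, j, s, v, l in rows]
        )

    def test_no_deficit_retains_everyone(self):
        frame = self._cohort_frame(20)
        assert len(kin.exclusion_filter(frame)) == 20

    def test_six_deficient_of_231_leaves_225(self):
        deficient = {f"P{i:03d}" for i in (3, 40, 77, 120, 200, 231)}
        frame = self._cohort_frame(231, deficient=deficient)
        retained = kin.exclusion_filter(frame)
        assert len(retained) == 225
        assert retained.isdisjoint(deficient)

    def test_missing_ee_class_drops_participant(self):
        frame = self._cohort_frame(5)
        frame = frame[
            ~((frame["participant_id"] == "P001") & (frame["label"] == "ee"))
        ]
        retained = kin.exclusion_filter(frame)
        assert "P001" not in retained and len(retained) == 4


def test_full_cohort_trials_all_valid(small_cohort):
    strokes = small_cohort["strokes"]
    trials = strokes.groupby(["participant_id", "condition", "trial"])
    counts = trials.size()
    assert (counts >= 10).all()
    assert strokes["trial_valid"].all()
    # LLee trials split 8 large / 8 small
    llee = strokes[strokes["condition"] == "LLee"]
    by_trial = llee.groupby(["participant_id", "trial"])["label"]
    assert (by_trial.apply(lambda s: (s == "LL").sum()) == 8).all()
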