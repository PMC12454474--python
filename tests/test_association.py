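"""Group F-tests, standardized-beta regressions and the 20-model battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopscale import association as assoc
from loopscale import scaling as sc
from loopscale import synthetic as syn
from loopscale.exceptions import CollinearityError, ConfigError


class TestGroupModel:
    def test_identical_outcomes_give_zero_F(self):
        groups = np.array(["HC"] * 5 + ["rMDD"] * 5 + ["cMDD"] * 5)
        res = assoc.fit_group_model(np.full(15, 2.0), groups)
        assert res.F == 0.0 and res.p == 1.0

    def test_two_level_F_equals_squared_t_on_50_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(5, 30, 2)
            y = np.concatenate([rng.normal(0, 1, n1), rng.normal(0.4, 1, n2)])
            groups = np.array(["HC"] * n1 + ["rMDD"] * n2)
            res = assoc.fit_group_model(y, groups, coding="lifetime")
            t, p = stats.ttest_ind(y[:n1], y[n1:], equal_var=True)
            assert res.F == pytest.approx(t**2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-12)
            assert (res.df1, res.df2) == (1, n1 + n2 - 2)

    def test_empty_group_raises(self):
        groups = np.array(["HC"] * 5 + ["rMDD"] * 5)
        with pytest.raises(ConfigError):
            assoc.fit_group_model(np.arange(10.0), groups, coding="three_level")

    def test_lifetime_collapses_mdd_groups(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 30)
        groups = np.array(["HC"] * 10 + ["rMDD"] * 10 + ["cMDD"] * 10)
        res = assoc.fit_group_model(y, groups, coding="lifetime")
        collapsed = np.array(["HC"] * 10 + ["MDD"] * 20)
        t, _ = stats.ttest_ind(y[groups == "HC"], y[collapsed == "MDD"])
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_null_type_one_error_nominal(self):
        """Under the null generator (no group effect) the 3-level F test
        rejects at close to the nominal 5% rate."""
        cfg = syn.with_overrides(
            syn.CohortConfig(), anhedonia_vs_effect=0.0
        )
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            truth = syn.draw_cohort_subjects(cfg, rng)
            res = assoc.fit_group_model(
                truth["scaling_gain"].to_numpy(), truth["group"].to_numpy()
            )
            rejections += res.p < 0.05
        assert 0.036 <= rejections / reps <= 0.065


class TestDimensionalModel:
    def test_single_predictor_beta_is_pearson_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, 60)
        y = 0.4 * x + rng.normal(0, 1, 60)
        res = assoc.fit_dimensional_model(y, pd.DataFrame({"anhedonia": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert res.betas["anhedonia"][0] == pytest.approx(r, abs=1e-12)

    def test_two_predictor_betas_match_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            x1 = rng.normal(0, 1, n)
            x2 = 0.5 * x1 + rng.normal(0, 1, n)
            y = 0.3 * x1 - 0.2 * x2 + rng.normal(0, 1, n)
            res = assoc.fit_dimensional_model(
                y, pd.DataFrame({"a": x1, "b": x2})
            )
            # closed form: beta = R^-1 r on standardized variables
            z = lambda v: (v - v.mean()) / v.std(ddof=1)
            Z = np.column_stack([z(x1), z(x2)])
            R = np.corrcoef(Z, rowvar=False)
            rvec = np.array([np.corrcoef(z(y), Z[:, k])[0, 1] for k in range(2)])
            expected = np.linalg.inv(R) @ rvec
            assert res.betas["a"][0] == pytest.approx(expected[0], abs=1e-10)
            assert res.betas["b"][0] == pytest.approx(expected[1], abs=1e-10)

    def test_betas_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 10, 80)
        y = rng.normal(0, 1, 80) + 0.02 * x
        a = assoc.fit_dimensional_model(y, pd.DataFrame({"s": x}))
        b = assoc.fit_dimensional_model(
            3.5 * y - 2, pd.DataFrame({"s": -0.1 * x + 400})
        )
        assert abs(a.betas["s"][0]) == pytest.approx(abs(b.betas["s"][0]), abs=1e-12)
        assert a.betas["s"][1] == pytest.approx(b.betas["s"][1], abs=1e-12)

    def test_perfect_collinearity_raises(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 30)
        with pytest.raises(CollinearityError):
            assoc.fit_dimensional_model(
                rng.normal(0, 1, 30), pd.DataFrame({"a": x, "b": 2 * x})
            )

    def test_joint_beta_approaches_simple_beta_without_predictor_overlap(self):
        """With uncorrelated predictors the joint anhedonia beta equals the
        simple one; at r = 0.55 they differ more."""
        diffs = {}
        for r_target in (0.0, 0.55):
            cfg = syn.CohortConfig(
                n_hc=2000, n_rmdd=2000, n_cmdd=1000,
                depression_anhedonia_corr=r_target,
                group_depression_means=(30.0, 30.0, 30.0),
                group_wellbeing_means=(22.0, 22.0, 22.0),
                seed=8,
            )
            truth = syn.draw_cohort_subjects(cfg, np.random.default_rng(8))
            y = truth["scaling_gain"].to_numpy()
            simple = assoc.fit_dimensional_model(
                y, truth[["anhedonia"]]
            ).betas["anhedonia"][0]
            joint = assoc.fit_dimensional_model(
                y, truth[["anhedonia", "general_depression"]]
            ).betas["anhedonia"][0]
            diffs[r_target] = abs(joint - simple)
        assert diffs[0.0] < 0.02
        assert diffs[0.0] < diffs[0.55]


@pytest.fixture(scope="module")
def battery_inputs():
        cfg = syn.CohortConfig(n_hc=25, n_rmdd=25, n_cmdd=20, seed=10)
        rng = np.random.default_rng(10)
        truth = syn.draw_cohort_subjects(cfg, rng)
        vs_rows = []
        vel_rows = []
        for design in ("LL", "LLee"):
            peaks, sizes, dummy, _ = syn.simulate_design_measurements(
                cfg, design, rng, truth=truth
            )
            slopes, coefs = sc.vs_slopes_batched(peaks, dummy, sizes)
            small_cls, large_cls = ("LL1", "LL4") if design == "LL" else ("ee", "LL")
            for i, pid in enumerate(truth["participant_id"]):
                vs_rows.append(
                    {"participant_id": pid, "design": design,
                     "slope": slopes[i], "intercept": 0.0,
                     "size_coefficient": coefs[i],
                     "n_segments": peaks.shape[1], "slope_z": np.nan}
                )
                vel_rows.append(
                    {"participant_id": pid, "segment_class": small_cls,
                     "mean_peak_velocity_cm_s": peaks[i, dummy == 0].mean(),
                     "n_segments": int((dummy == 0).sum())}
                )
                vel_rows.append(
                    {"participant_id": pid, "segment_class": large_cls,
                     "mean_peak_velocity_cm_s": peaks[i, dummy == 1].mean(),
                     "n_segments": int((dummy == 1).sum())}
                )
        records = truth[["participant_id", "group"]].assign(
            wellbeing_total=-truth["anhedonia"],
            general_depression_total=truth["general_depression"],
        )
        return pd.DataFrame(vs_rows), pd.DataFrame(vel_rows), records


class TestBattery:
    def test_registry_has_20_models(self):
        assert assoc.N_BATTERY_MODELS == 20
        kinds = pd.Series([m[3] for m in assoc.MODEL_REGISTRY]).value_counts()
        assert kinds["group"] == 8
        assert kinds["dimensional"] == 10
        assert kinds["joint"] == 2

    def test_battery_runs_all_models_deterministically(self, battery_inputs):
        vs, vel, records = battery_inputs
        res1 = assoc.run_battery(vs, vel, records)
        res2 = assoc.run_battery(vs, vel, records)
        assert len(res1) == 20
        assert res1["model"].is_unique
        pd.testing.assert_frame_equal(res1, res2)
        csv1, csv2 = res1.to_csv(index=False), res2.to_csv(index=False)
        assert csv1 == csv2

    def test_listwise_deletion_logged_per_model(self, battery_inputs):
        vs, vel, records = battery_inputs
        records = records.copy()
        records.loc[records.index[:3], "wellbeing_total"] = np.nan
        res = assoc.run_battery(vs, vel, records)
        anh = res[res["model"] == "LL_vs_anhedonia"].iloc[0]
        grp = res[res["model"] == "LL_vs_group3"].iloc[0]
        assert anh["n_dropped"] == 3 and anh["n"] == grp["n"] - 3

    def test_empty_join_raises(self, battery_inputs):
        vs, vel, records = battery_inputs
        other = records.copy()
        other["participant_id"] = "X" + other["participant_id"]
        with pytest.raises(ConfigError):
            assoc.run_battery(vs, vel, other)
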