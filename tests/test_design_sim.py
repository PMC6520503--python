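"""Trial schedules, subject sampling, gains, traces and hit simulation."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

from reachgain import design_sim as ds
from reachgain.models import predictor
from reachgain.preprocess import response_gain


def _counts(records, **filters):
    n = 0
    for r in records:
        if all(getattr(r, k) == v for k, v in filters.items()):
            n += 1
    return n


class TestBlockSchedules:
    def test_experiment1_composition(self):
        condition = ds.experiment_conditions(1)[0]
        recs = ds.build_block_schedule(1, condition, seed=3)
        assert len(recs) == 102
        assert _counts(recs, phase="context") == 18
        # context: 6 standard unperturbed reaches per target
        for target in ("left", "center", "right"):
            assert _counts(recs, phase="context", cued_target=target,
                           trial_type="standard", jump_direction="none") == 6
        # 36 unperturbed main trials, 6 of them channel trials to center
        assert _counts(recs, phase="main", jump_direction="none") == 36
        assert _counts(recs, phase="main", jump_direction="none",
                       trial_type="channel", cued_target="center") == 6
        # 48 jump trials: per direction 12 outer + 12 center, 6 channel
        for d, outer in (("left", "left"), ("right", "right")):
            assert _counts(recs, phase="main", jump_direction=d) == 24
            assert _counts(recs, phase="main", jump_direction=d,
                           cued_target=outer) == 12
            assert _counts(recs, phase="main", jump_direction=d,
                           trial_type="channel") == 6

    @pytest.mark.parametrize("cond_idx, total, n_unpert, n_center_chan", [
        (0, 112, 40, 10),   # center more probable
        (1, 122, 50, 5),    # outer targets more probable
    ])
    def test_experiment2_composition(self, cond_idx, total, n_unpert,
                                     n_center_chan):
        condition = ds.experiment_conditions(2)[cond_idx]
        recs = ds.build_block_schedule(2, condition, seed=5)
        assert len(recs) == total
        assert _counts(recs, phase="context") == 12
        assert _counts(recs, phase="main", jump_direction="none") == n_unpert
        assert _counts(recs, phase="main", jump_direction="none",
                       trial_type="channel") == n_center_chan
        for d in ("left", "right"):
            assert _counts(recs, phase="main", jump_direction=d) == 30

    @pytest.mark.parametrize("condition", ds.experiment_conditions(3),
                             ids=lambda c: c.condition_id)
    def test_experiment3_composition(self, condition):
        recs = ds.build_block_schedule(3, condition, seed=7)
        assert len(recs) == 136
        assert _counts(recs, phase="context") == 18
        main = [r for r in recs if r.phase == "main"]
        assert len(main) == 118
        assert _counts(main, jump_direction="none") == 10
        assert _counts(main, jump_direction="none", trial_type="channel") == 5
        n_jump = sum(r.jump_direction != "none" for r in main)
        assert n_jump == 108
        assert _counts(main, trial_type="channel") - 5 == 36  # jump channels
        # cue counts per direction follow the probability ratio
        p = condition.prob_ratio
        for d, outer in (("left", "left"), ("right", "right")):
            n_dir = _counts(main, jump_direction=d)
            n_outer = _counts(main, jump_direction=d, cued_target=outer)
            assert n_dir == 54
            assert n_outer / (n_dir - n_outer) == pytest.approx(p)

    def test_context_first_then_seeded_shuffle(self):
        condition = ds.experiment_conditions(3)[0]
        a = ds.build_block_schedule(3, condition, seed=1)
        b = ds.build_block_schedule(3, condition, seed=1)
        c = ds.build_block_schedule(3, condition, seed=2)
        assert a == b                       # bit-reproducible
        assert [r.phase for r in a[:18]] == ["context"] * 18
        key = lambda recs: [(r.trial_type, r.jump_direction, r.cued_target)
                            for r in recs]
        assert key(a) != key(c)             # different order
        assert sorted(key(a)) == sorted(key(c))  # same composition

    def test_schedule_errors(self):
        cond3 = ds.experiment_conditions(3)[0]
        with pytest.raises(ValueError):
            ds.build_block_schedule(4, cond3, seed=0)
        with pytest.raises(ValueError):
            ds.build_block_schedule(1, cond3, seed=0)  # wrong experiment
        off_grid = ds.ConditionDesign("custom", 3, 3.0, 1.0, 0.5, 0.5,
                                      (0.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            ds.build_block_schedule(3, off_grid, seed=0)

    def test_value_grid_has_8_conditions_and_5_relative_values(self):
        conditions = ds.experiment_conditions(3)
        assert len(conditions) == 8
        values = sorted({c.relative_value for c in conditions})
        assert values == pytest.approx([0.25, 0.5, 1.0, 2.0, 4.0])


class TestConditionDesign:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ds.ConditionDesign("bad", 1, -1.0, 1.0, 0.5, 0.5, (1/3,) * 3)
        with pytest.raises(ValueError):
            ds.ConditionDesign("bad", 1, 1.0, 1.0, 0.6, 0.6, (1/3,) * 3)
        with pytest.raises(ValueError):
            ds.ConditionDesign("bad", 1, 1.0, 1.0, 0.5, 0.5, (0.5, 0.1, 0.1))

    def test_trial_record_cue_consistency(self):
        with pytest.raises(ValueError):
            ds.TrialRecord("s", "b", 0, "main", "standard", "left", "right",
                           "c")


class TestSubjectSampling:
    def test_zero_sd_returns_group_means(self):
        subs = ds.sample_subject_params(
            group_sds={"intercept": 0.0, "slope": 0.0, "risk_weight": 0.0},
            n_subjects=4, seed=0)
        gp = ds.DEFAULT_GROUP_PARAMS
        for s in subs:
            assert s.intercept == gp.intercept_mean
            assert s.slope == gp.slope_mean
            assert s.risk_weight == gp.risk_weight_mean

    def test_seeded_reproducibility(self):
        a = ds.sample_subject_params(n_subjects=12, seed=5)
        b = ds.sample_subject_params(n_subjects=12, seed=5)
        assert a == b
        assert len(a) == 12

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ds.sample_subject_params(group_sds={"slope": -0.1}, n_subjects=2)

    def test_truncated_weight_mean_matches_quadrature(self):
        mu, sd = 0.68, 0.1
        subs = ds.sample_subject_params(
            {"risk_weight": mu}, {"risk_weight": sd, "intercept": 0.3,
                                  "slope": 0.15},
            n_subjects=100_000, seed=9)
        empirical = np.mean([s.risk_weight for s in subs])
        # independent oracle: normalized first moment by quadrature
        dens = lambda w: np.exp(-0.5 * ((w - mu) / sd) ** 2)
        z, _ = integrate.quad(dens, 0, 1)
        m1, _ = integrate.quad(lambda w: w * dens(w), 0, 1)
        assert empirical == pytest.approx(m1 / z, abs=0.01)


class TestExpectedGain:
    def test_neutral_condition_returns_intercept(self):
        cond = ds.ConditionDesign("c", 3, 1.0, 1.0, 0.5, 0.5, (0, 1, 0))
        s = ds.SubjectParams("s", 1.3, -0.7, 0.4, 0.5)
        for model in ("probability", "reward", "value_neutral", "value_risk"):
            assert ds.expected_gain(s, cond, model) == pytest.approx(1.3)

    def test_risk_neutral_weight_reduces_to_value_model(self, exp3_conditions):
        s = ds.SubjectParams("s", 0.9, -0.45, 0.5, 0.5)
        for cond in exp3_conditions:
            assert ds.expected_gain(s, cond, "value_risk") == pytest.approx(
                ds.expected_gain(s, cond, "value_neutral"))

    def test_pure_probability_weighting(self):
        # alpha=0, beta=1, w=1 with r=2, p=0.5: predictor = 2 ln 0.5
        cond = ds.ConditionDesign("c", 3, 2.0, 1.0, 1 / 3, 2 / 3, (0, 1, 0))
        s = ds.SubjectParams("s", 0.0, 1.0, 1.0, 0.5)
        assert ds.expected_gain(s, cond, "value_risk") == pytest.approx(
            2 * np.log(0.5), abs=1e-4)


class TestGainTable:
    def test_cell_count(self, exp3_conditions):
        subs = ds.sample_subject_params(n_subjects=10, seed=1)
        gains = ds.simulate_gain_table(exp3_conditions, subs, 18, seed=2)
        assert len(gains) == 8 * 10 * 2

    def test_zero_noise_equals_expected(self, exp3_conditions):
        subs = [ds.SubjectParams("s1", 1.0, -0.4, 0.7, 0.0),
                ds.SubjectParams("s2", 0.8, -0.3, 0.6, 0.0)]
        lookup = {c.condition_id: c for c in exp3_conditions}
        for g in ds.simulate_gain_table(exp3_conditions, subs, 18, seed=3):
            sub = subs[0] if g.subject_id == "s1" else subs[1]
            assert g.gain == pytest.approx(
                ds.expected_gain(sub, lookup[g.condition_id]), abs=1e-12)

    def test_cell_variance_matches_closed_form(self, exp3_conditions):
        # 10^4 replicate cells realized as identical-parameter subjects
        noise_sd, n_trials = 0.5, 18
        subs = [ds.SubjectParams(f"s{i}", 1.0, -0.4, 0.68, noise_sd)
                for i in range(10_000)]
        gains = ds.simulate_gain_table(exp3_conditions[:1], subs, n_trials,
                                       seed=4, directions=("left",))
        var = np.var([g.gain for g in gains], ddof=1)
        assert var == pytest.approx(noise_sd**2 / n_trials, rel=0.05)

    def test_empty_conditions_rejected(self):
        subs = ds.sample_subject_params(n_subjects=2, seed=0)
        with pytest.raises(ValueError):
            ds.simulate_gain_table([], subs, 18, seed=0)


class TestTraces:
    def test_zero_gain_zero_noise_is_flat(self):
        ts = ds.synthesize_trace(0.0, noise_sd=0.0)
        assert np.all(ts.values == 0)

    def test_window_mean_equals_gain_exactly(self):
        ts = ds.synthesize_trace(1.0, noise_sd=0.0)
        assert response_gain(ts).gain == pytest.approx(1.0, abs=1e-9)

    def test_zero_before_onset_monotone_after(self):
        ts = ds.synthesize_trace(2.0, onset=125, rise_time=60, noise_sd=0.0)
        assert np.all(ts.values[ts.t <= 125] == 0)
        post = ts.values[ts.t > 125]
        assert np.all(np.diff(post) >= 0)

    def test_noisy_average_converges_to_gain(self):
        means = [response_gain(ds.synthesize_trace(1.0, noise_sd=0.5,
                                                   seed=i)).gain
                 for i in range(500)]
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ds.synthesize_trace(1.0, rise_time=0.0)
        with pytest.raises(ValueError):
            ds.synthesize_trace(1.0, onset=600.0, duration=500.0)


class TestHits:
    def test_zero_slope_rate_is_logistic_intercept(self):
        a = 0.8
        draws = ds.simulate_hits(np.zeros(20_000), (a, 0.0), seed=1)
        assert draws.mean() == pytest.approx(expit(a), abs=0.01)

    def test_binomial_oracle_at_fixed_gain(self):
        a, b, g, n = 1.0, 1.2, -0.6, 10_000
        p = expit(a + b * g)
        draws = ds.simulate_hits(np.full(n, g), (a, b), seed=2)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(draws.mean() - p) < 2 * se

    def test_steep_slope_thresholds_on_gain(self):
        params = (0.0, 1e6)
        assert ds.simulate_hits(1.0, params, seed=3)
        assert not ds.simulate_hits(-1.0, params, seed=3)

    def test_default_calibration_near_paper_rate(self):
        a, b = ds.default_hit_params()
        assert b > 0
        # the calibration target is the pooled standard-trial hit rate
        rng = np.random.default_rng(0)
        subs = ds.sample_subject_params(n_subjects=30, seed=12)
        rates = []
        for exp in (1, 2, 3):
            conds = ds.experiment_conditions(exp)
            trials = []
            for si, s in enumerate(subs[:6]):
                for ci, c in enumerate(conds):
                    recs = ds.build_block_schedule(
                        exp, c, seed=100 * si + ci, subject_id=s.subject_id,
                        block_id=f"b{ci}")
                    trials.append(ds.schedule_to_frame(recs))
            import pandas as pd
            df = ds.simulate_trial_hits(pd.concat(trials, ignore_index=True),
                                        subs[:6], conds, seed=exp)
            std = df[(df.trial_type == "standard")
                     & (df.jump_direction != "none") & (df.phase == "main")]
            rates.append(std["hit"].astype(float).mean())
        pooled = np.mean(rates)
        assert pooled == pytest.approx(0.738, abs=0.06)


class TestGeneratorRecoversSlope:
    def test_regression_on_generating_predictor_recovers_beta(self,
                                                              exp3_conditions):
        subs = ds.sample_subject_params(n_subjects=12, seed=21)
        gains = ds.simulate_gain_table(exp3_conditions, subs, 18, seed=22,
                                       model="value_neutral")
        lookup = {c.condition_id: c for c in exp3_conditions}
        slopes = []
        for s in subs:
            rows = [g for g in gains if g.subject_id == s.subject_id]
            x = np.array([predictor(lookup[g.condition_id], "value_neutral")
                          for g in rows])
            y = np.array([g.gain for g in rows])
            slopes.append(np.polyfit(x, y, 1)[0])
        mean_slope = np.mean(slopes)
        sem = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean_slope - ds.DEFAULT_GROUP_PARAMS.slope_mean) < 3 * sem


class TestCohort:
    def test_cohort_tables_consistent(self):
        cohort = ds.simulate_cohort(1, n_subjects=3, seed=8)
        trials = cohort["trials"]
        assert trials.groupby(["subject_id", "block_id"]).size().eq(102).all()
        assert set(trials["condition_id"]) == {
            c.condition_id for c in ds.experiment_conditions(1)}
        # hits filled exactly on main standard jump trials
        std = ((trials.trial_type == "standard")
               & (trials.jump_direction != "none") & (trials.phase == "main"))
        assert trials.loc[std, "hit"].notna().all()
        assert trials.loc[~std, "hit"].isna().all()
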