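"""QUEST staircases, simulated observers, and the scanner sampling rule."""

import math

import numpy as np
import pytest

from stereosim.psychophys import (FALLBACK_SNR, PsychometricObserver, QuestState,
                                  SamplingRange, StaircaseProtocol, TrialRecord,
                                  condition_thresholds, derive_fmri_sampling_range,
                                  make_quest, quest_recommend, quest_update,
                                  run_session, run_staircase, sample_trial_snr,
                                  weibull_prob)


def hand_weibull(x, alpha, beta=3.5, gamma=0.5, lapse=0.01, criterion=0.82):
    """Independent re-derivation of the criterion-anchored Weibull."""
    t = alpha - math.log10(math.log((1 - gamma - lapse) / (1 - lapse - criterion))) / beta
    return gamma + (1 - gamma - lapse) * (1 - math.exp(-(10 ** (beta * (x - t)))))


class TestQuestUpdate:
    def test_three_point_grid_matches_hand_computed_bayes(self):
        grid = np.array([-1.0, -0.5, 0.0])
        state = QuestState(grid=grid, posterior=np.ones(3) / 3)
        quest_update(state, 1.0, "correct")  # x = log10(1.0) = 0
        likes = np.array([hand_weibull(0.0, a) for a in grid])
        expected = (likes / 3) / (likes / 3).sum()
        assert np.allclose(state.posterior, expected, atol=1e-12)

    def test_timeout_scored_as_incorrect(self):
        grid = np.linspace(-1, 0, 11)
        s1 = QuestState(grid=grid, posterior=np.ones(11))
        s2 = QuestState(grid=grid, posterior=np.ones(11))
        quest_update(s1, 0.5, "incorrect")
        quest_update(s2, 0.5, "timeout")
        assert np.allclose(s1.posterior, s2.posterior)

    def test_posterior_normalized_after_64_sequential_updates(self):
        state = make_quest(0.8)
        rng = np.random.default_rng(0)
        for i in range(64):
            quest_update(state, float(rng.uniform(0.05, 1.0)),
                         "correct" if rng.random() < 0.7 else "incorrect")
        assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(state.history) == 64

    def test_history_is_append_only(self):
        state = make_quest(0.8)
        quest_update(state, 0.8, "correct")
        first = state.history[0]
        quest_update(state, 0.5, "incorrect")
        assert state.history[0] is first
        assert isinstance(first, TrialRecord)

    def test_bad_outcome_rejected(self):
        state = make_quest(0.8)
        with pytest.raises(ValueError):
            quest_update(state, 0.5, "maybe")


class TestQuestRecommend:
    def test_delta_posterior_recommends_criterion_point(self):
        grid = np.linspace(-1, 0, 101)
        post = np.zeros(101)
        post[40] = 1.0
        state = QuestState(grid=grid, posterior=post)
        assert quest_recommend(state) == pytest.approx(10 ** grid[40])

    def test_recommendation_clipped_to_physical_snr_range(self):
        grid = np.linspace(0.5, 1.5, 11)  # posterior implies SNR > 1
        state = QuestState(grid=grid, posterior=np.ones(11))
        assert quest_recommend(state) == 1.0

    def test_recommendation_nonincreasing_under_all_correct_responses(self):
        state = make_quest(0.8)
        prev = np.inf
        for _ in range(40):
            x = quest_recommend(state)
            assert x <= prev + 1e-12
            prev = x
            quest_update(state, x, "correct")


class TestStaircase:
    def test_history_has_four_practice_and_sixty_test_trials(self):
        obs = PsychometricObserver(threshold_alpha=np.log10(0.4))
        res = run_staircase(obs, StaircaseProtocol(task="snr"), seed=0)
        assert len(res.history) == 64
        assert sum(t.phase == "practice" for t in res.history) == 4
        assert sum(t.phase == "test" for t in res.history) == 60

    def test_step_observer_recovered_within_grid_resolution(self):
        # near-deterministic observer: steep slope, no lapse
        obs = PsychometricObserver(threshold_alpha=np.log10(0.3),
                                   slope_beta=40.0, lapse_lambda=0.0)
        res = run_staircase(obs, StaircaseProtocol(task="snr"), seed=1)
        assert abs(np.log10(res.estimate.value) - obs.threshold_alpha) < 0.08

    def test_monte_carlo_threshold_recovery(self):
        obs = PsychometricObserver(threshold_alpha=np.log10(0.4))
        ests = [np.log10(run_staircase(obs, StaircaseProtocol(task="snr"),
                                       seed=s).estimate.value)
                for s in range(120)]
        assert abs(np.mean(ests) - obs.threshold_alpha) < 0.05

    def test_recovery_bias_small_across_alpha_grid(self):
        for alpha in np.log10([0.15, 0.3, 0.5, 0.7]):
            obs = PsychometricObserver(threshold_alpha=alpha)
            ests = [np.log10(run_staircase(obs, StaircaseProtocol(task="snr"),
                                           seed=s).estimate.value)
                    for s in range(40)]
            assert abs(np.mean(ests) - alpha) < 0.05

    def test_criterion_consistency_at_true_alpha(self):
        obs = PsychometricObserver(threshold_alpha=np.log10(0.4))
        rng = np.random.default_rng(3)
        n = 10_000
        p = obs.p_correct(obs.threshold_alpha)
        hits = (rng.random(n) < p).sum()
        assert abs(hits / n - 0.82) < 3 * math.sqrt(0.82 * 0.18 / n) + 0.005

    def test_feature_task_staircase_recovers_offset_threshold(self):
        obs = PsychometricObserver(threshold_alpha=np.log10(40.0))  # 40 arcsec
        ests = [np.log10(run_staircase(obs, StaircaseProtocol(task="feature"),
                                       seed=s).estimate.value)
                for s in range(60)]
        assert abs(np.mean(ests) - obs.threshold_alpha) < 0.05

    def test_nonresponses_occur_and_are_scored_incorrect(self):
        obs = PsychometricObserver(threshold_alpha=np.log10(0.4),
                                   nonresponse_rate=0.3)
        res = run_staircase(obs, StaircaseProtocol(task="snr"), seed=5)
        outcomes = {t.outcome for t in res.history}
        assert "timeout" in outcomes


class TestSession:
    def test_session_yields_six_runs_and_twelve_estimates(self):
        obs = {c: PsychometricObserver(threshold_alpha=np.log10(0.4))
               for c in ("upright", "inverted", "random")}
        table, results = run_session(obs, seed=0)
        assert len(table) == 12
        assert table.run.nunique() == 6
        assert len(results) == 12
        assert set(table.condition.value_counts()) == {4}

    def test_interleaving_alternates_staircase_ids(self):
        obs = {c: PsychometricObserver(threshold_alpha=np.log10(0.4))
               for c in ("upright", "inverted", "random")}
        table, _ = run_session(obs, seed=1)
        for schedule in table.attrs["interleave_schedules"].values():
            ids = sorted(set(schedule))
            assert len(ids) == 2
            assert all(schedule[i] != schedule[i + 1] for i in range(len(schedule) - 1))
            assert len(schedule) == 128

    def test_identical_observers_give_equal_condition_thresholds(self):
        obs = {c: PsychometricObserver(threshold_alpha=np.log10(0.4))
               for c in ("upright", "inverted", "random")}
        means = []
        for seed in range(12):
            table, _ = run_session(obs, seed=seed)
            means.append(condition_thresholds(table))
        grand = np.array(means)
        spread = grand.mean(axis=0).max() - grand.mean(axis=0).min()
        assert spread < 0.05  # Monte-Carlo error at 12 sessions x 4 staircases


class TestScannerSamplingRule:
    @staticmethod
    def _history(values, phase="test"):
        return [TrialRecord(i, phase, float(v), "correct")
                for i, v in enumerate(values)]

    def test_constant_last_thirty_gives_zero_width_range(self):
        hist = self._history([0.5] * 35)
        r = derive_fmri_sampling_range(hist)
        assert (r.low, r.high) == (0.5, 0.5)
        assert not r.fallback

    def test_mean_and_sd_match_hand_computation(self):
        vals = np.linspace(0.41, 0.47, 30)  # nearly flat trend, slope 0.002/trial
        hist = self._history(vals)
        r = derive_fmri_sampling_range(hist)
        assert r.low == pytest.approx(vals.mean() - vals.std(ddof=1))
        assert r.high == pytest.approx(vals.mean() + vals.std(ddof=1))

    def test_drifting_staircase_falls_back_to_80_percent(self):
        vals = np.linspace(0.8, 0.3, 30)  # steep downward trend, no asymptote
        r = derive_fmri_sampling_range(self._history(vals))
        assert r.fallback
        assert sample_trial_snr(r, seed=0) == FALLBACK_SNR == 0.8

    def test_floor_hugging_posterior_triggers_fallback(self):
        state = make_quest(0.8)
        state.posterior = np.zeros_like(state.posterior)
        state.posterior[0] = 1.0  # all mass at the grid floor
        hist = self._history([0.5] * 30)
        assert derive_fmri_sampling_range(hist, state).fallback

    def test_too_few_test_trials_rejected(self):
        with pytest.raises(ValueError):
            derive_fmri_sampling_range(self._history([0.5] * 29))

    def test_practice_trials_excluded_from_last_thirty(self):
        hist = (self._history([0.9] * 4, phase="practice")
                + self._history([0.5] * 30))
        r = derive_fmri_sampling_range(hist)
        assert (r.low, r.high) == (0.5, 0.5)


class TestSampleTrialSnr:
    def test_degenerate_range_returns_value(self):
        assert sample_trial_snr(SamplingRange(0.4, 0.4), seed=0) == 0.4

    def test_draws_stay_in_range_with_correct_mean(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_trial_snr(SamplingRange(0.2, 0.6), rng)
                          for _ in range(10_000)])
        assert draws.min() >= 0.2 and draws.max() <= 0.6
        assert abs(draws.mean() - 0.4) < 0.01

    def test_draws_clipped_to_unit_interval(self):
        rng = np.random.default_rng(2)
        draws = np.array([sample_trial_snr(SamplingRange(0.9, 1.3), rng)
                          for _ in range(500)])
        assert draws.max() <= 1.0


def test_weibull_hits_criterion_exactly_at_alpha():
    for alpha in (-0.6, -0.3, 0.0):
        assert weibull_prob(alpha, alpha) == pytest.approx(0.82, abs=1e-12)
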