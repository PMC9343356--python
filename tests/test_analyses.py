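import numpy as np
import pytest

from betwheel.analyses import (
    BettingGameModel,
    adjacent_bet_spread,
    average_aligned_profile,
    bet_order_analysis,
    ks_analysis,
    profile_pseudo_sample,
    profile_vs_error_ks,
    spread_error_analysis,
    undo_summary,
)
from betwheel.observers import Dataset, ObserverParams, Trial, UndoEvent, simulate_dataset
from betwheel.profile_engine import PenaltyParams, build_profile, stacked_peak
from betwheel.circular import rotate_profile


def make_trial(target, bets, pid=0, idx=0, undo=None):
    return Trial(pid, idx, float(target), tuple(float(b) for b in bets),
                 experiment=2 if undo else 1, undo_event=undo)


class TestAdjacentBetSpread:
    def test_constant_steps(self):
        t = make_trial(0, [0, 10, 20, 30, 40, 50])
        assert adjacent_bet_spread(t) == pytest.approx(10.0)

    def test_identical_bets(self):
        assert adjacent_bet_spread(make_trial(0, [7] * 6)) == 0.0

    def test_wraparound_steps(self):
        t = make_trial(0, [355, 5, 15, 25, 35, 45])
        assert adjacent_bet_spread(t) == pytest.approx(10.0)


class TestAverageAlignedProfile:
    def test_single_trial_is_its_aligned_profile(self):
        t = make_trial(200, [195, 198, 200, 202, 205, 210])
        avg = average_aligned_profile([t])
        expected = rotate_profile(build_profile(t.bets, PenaltyParams()), 200)
        assert np.allclose(avg, expected)

    def test_duplication_invariance(self):
        t = make_trial(100, [95, 98, 100, 102, 105, 110])
        assert np.allclose(average_aligned_profile([t]), average_aligned_profile([t, t]))

    def test_on_target_bets_peak_at_zero_and_match_scalar_recursion(self):
        trials = [make_trial(tg, [tg] * 6) for tg in (10, 120, 300)]
        avg = average_aligned_profile(trials)
        assert np.argmax(avg) == 0
        assert avg[0] == pytest.approx(stacked_peak(0.1), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_aligned_profile([])


class TestSpreadError:
    def test_degenerate_spread_participant_excluded(self):
        # participant 99: identical (stacked) bets on every trial -> spread
        # has zero variance and the correlation is undefined
        rng = np.random.default_rng(0)
        trials = []
        for i in range(30):
            e = float(rng.normal(0, 10) % 360)
            trials.append(make_trial(0, np.full(6, e), pid=99, idx=i))
        ds_good = simulate_dataset(3, 40, seed=8)
        all_trials = trials + ds_good.trials
        with pytest.warns(UserWarning, match="zero variance"):
            res = spread_error_analysis(Dataset(all_trials))
        assert 99 in res.excluded
        assert len(res.per_participant) == 3

    def test_confidence_coupled_observers_show_positive_mean_z(self):
        ds = simulate_dataset(
            8, 120, seed=77,
            base_params=ObserverParams(kind="discrete_confidence", confidence_coupling=0.6),
        )
        res = spread_error_analysis(ds)
        assert res.mean_z > 0
        assert res.group_test.p < 0.05

    def test_fixed_spread_discrete_observers_are_null(self):
        ds = simulate_dataset(8, 120, seed=78, kind="discrete")
        res = spread_error_analysis(ds)
        assert res.group_test.p > 0.05

    def test_profile_spread_measures_run(self, small_sampling_dataset):
        res = spread_error_analysis(small_sampling_dataset, "profile_sd")
        assert len(res.per_participant) == 6
        res2 = spread_error_analysis(small_sampling_dataset, "profile_iqr")
        assert np.isfinite(res2.mean_z)


class TestProfileVsErrorKS:
    def test_pseudo_sample_consistency_with_profile_distribution(self):
        # random draws from the profile's own distribution vs the
        # deterministic pseudo-sample: D stays at KS-null scale and
        # shrinks as n grows
        from betwheel.stats import ks_two_sample

        rng = np.random.default_rng(4)
        trials = [
            make_trial(0, rng.normal(0, 8, 6) % 360, idx=i) for i in range(50)
        ]
        prof = average_aligned_profile(trials)
        pool = profile_pseudo_sample(prof, 20000)
        ds = []
        for n in (100, 2000):
            a = rng.choice(pool, n)
            ds.append(ks_two_sample(a, profile_pseudo_sample(prof, n)).statistic)
        assert ds[0] < 0.2
        assert ds[1] < ds[0]

    def test_min_trials_enforced(self):
        trials = [make_trial(0, [0, 1, 2, 3, 4, 5])] * 5
        with pytest.raises(ValueError, match="at least 20"):
            profile_vs_error_ks(trials)

    def test_pseudo_sample_is_deterministic_and_spans_profile(self):
        prof = build_profile([100, 103, 98, 101, 99, 102], PenaltyParams())
        aligned = rotate_profile(prof, 100)
        s1 = profile_pseudo_sample(aligned, 50)
        s2 = profile_pseudo_sample(aligned, 50)
        assert np.array_equal(s1, s2)
        assert np.all(np.diff(s1) >= 0)
        assert -30 < s1[0] and s1[-1] < 30

    def test_flip_detects_one_sided_bet_placement(self):
        # bets placed exclusively clockwise of the target: mirroring the
        # profile moves its mass to the counterclockwise side, so D jumps;
        # symmetric placement is flip-insensitive
        rng = np.random.default_rng(9)
        skewed = [
            make_trial(100, (100 + np.abs(rng.normal(0, 10, 6))) % 360, idx=i)
            for i in range(80)
        ]
        sym = [
            make_trial(100, (100 + rng.normal(0, 10, 6)) % 360, idx=i)
            for i in range(80)
        ]
        gap_skewed = (
            profile_vs_error_ks(skewed, flipped=True).statistic
            - profile_vs_error_ks(skewed).statistic
        )
        gap_sym = (
            profile_vs_error_ks(sym, flipped=True).statistic
            - profile_vs_error_ks(sym).statistic
        )
        assert gap_skewed > 0.5
        assert abs(gap_sym) < 0.2

    def test_flip_about_bet1_axis_runs(self, small_sampling_dataset):
        trials = small_sampling_dataset.trials_of(1)
        res = profile_vs_error_ks(trials, flipped=True, flip_axis="bet1")
        assert 0 <= res.statistic <= 1

    def test_continuous_variant_agrees_qualitatively(self, small_sampling_dataset):
        trials = small_sampling_dataset.trials_of(0)
        two = profile_vs_error_ks(trials, variant="pseudo_sample")
        one = profile_vs_error_ks(trials, variant="continuous")
        assert abs(two.statistic - one.statistic) < 0.1


class TestBetOrder:
    def test_near_noiseless_observer_has_flat_zero_curves(self):
        trials = [
            make_trial(tg, [tg] * 6, pid=p, idx=i)
            for p in range(3)
            for i, tg in enumerate(np.linspace(5, 355, 20))
        ]
        res = bet_order_analysis(Dataset(trials))
        assert np.allclose(res.individual_mean, 0.0)
        assert np.allclose(res.cumulative_mean, 0.0)
        assert res.anova_individual.statistic == 0.0

    def test_sampling_observer_rising_individual_falling_cumulative(self):
        ds = simulate_dataset(10, 150, seed=91, kind="sampling")
        res = bet_order_analysis(ds)
        assert res.individual_mean[-1] > res.individual_mean[0]
        assert res.cumulative_mean[-1] < res.cumulative_mean[0]
        assert res.anova_individual.p < 0.05
        assert res.anova_cumulative.p < 0.05
        assert res.anova_individual.df == (5, 45)

    def test_degenerate_trials_excluded_with_warning(self):
        good = simulate_dataset(2, 30, seed=6).trials
        bad = make_trial(0, [0, 180, 0, 180, 0, 180], pid=0, idx=999)
        with pytest.warns(UserWarning, match="undefined cumulative"):
            res = bet_order_analysis(Dataset(good + [bad]))
        assert res.n_excluded_trials == 1


class TestUndoSummary:
    def test_no_undos(self, small_sampling_dataset):
        res = undo_summary(small_sampling_dataset)
        assert res.usage_rate == 0.0
        assert res.undone_mean_error is None

    def test_every_trial_undone(self):
        trials = [
            make_trial(0, [1, 2, 3, 4, 5, 6], idx=i, undo=UndoEvent(2, 90.0))
            for i in range(10)
        ]
        res = undo_summary(Dataset(trials))
        assert res.usage_rate == 1.0
        assert res.undone_mean_error == pytest.approx(90.0)
        assert res.by_bet_index == {3: 10}

    def test_lapse_driven_undos_near_chance(self, small_undo_dataset):
        res = undo_summary(small_undo_dataset)
        assert 0 < res.usage_rate < 1
        assert res.undone_mean_error == pytest.approx(90.0, abs=12.0)
        assert res.replacement_mean_error < res.undone_mean_error


class TestModelResults:
    def test_fit_summary_and_report(self, small_sampling_dataset):
        res = BettingGameModel(small_sampling_dataset).fit()
        text = res.summary()
        assert "Spread-error coupling" in text
        assert "cumulative" in text
        d = res.to_dict()
        assert set(d) >= {"spread_error", "bet_order", "ks", "undo"}
        assert len(d["bet_order"]["individual_mean_error"]) == 6
        assert 0 <= d["ks"]["mean_D"] <= 1
        import json

        json.dumps(d)  # report must be JSON-serializable

    def test_from_dataframe_roundtrip(self, small_sampling_dataset):
        from betwheel.io import frame_from_dataset

        df = frame_from_dataset(small_sampling_dataset)
        model = BettingGameModel.from_dataframe(df)
        assert len(model.dataset) == len(small_sampling_dataset)
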