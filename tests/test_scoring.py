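"""Activity and E-O scoring, validity rules, and group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from plateomr import (
    ScoreError,
    activity_percent,
    eo_statistic,
    score_larvae,
    summarize_group,
    row_means,
)


class TestActivityPercent:
    def test_all_moves_is_hundred(self):
        assert activity_percent([1] * 10) == 100.0

    def test_alternating_is_fifty(self):
        assert activity_percent([1, 0, 1, 0]) == 50.0

    def test_fraction_arithmetic(self):
        flags = [1] * 138 + [0] * 162  # 138 of 300 intervals
        assert activity_percent(flags) == pytest.approx(46.0)

    def test_empty_input_raises(self):
        with pytest.raises(ScoreError):
            activity_percent([])


class TestEOStatistic:
    def test_perfect_optomotor_response_is_plus_hundred(self):
        up = {p: 100.0 for p in (4, 6, 8, 10, 12)}
        up.update({p: 0.0 for p in (3, 5, 7, 9, 11)})
        assert eo_statistic(up) == 100.0

    def test_constant_occupancy_gives_zero(self):
        up = {p: 63.0 for p in range(3, 13)}
        assert eo_statistic(up) == 0.0

    def test_mean_difference_arithmetic(self):
        up = dict(zip((4, 6, 8, 10, 12), (80, 70, 60, 90, 100)))
        up.update(zip((3, 5, 7, 9, 11), (20, 30, 40, 10, 0)))
        assert eo_statistic(up) == pytest.approx(60.0)

    def test_swapping_period_labels_flips_the_sign(self):
        rng = np.random.default_rng(0)
        up = {p: rng.uniform(0, 100) for p in range(3, 13)}
        forward = eo_statistic(up)
        swapped = eo_statistic(up, even=(3, 5, 7, 9, 11), odd=(4, 6, 8, 10, 12))
        assert swapped == pytest.approx(-forward)

    def test_undefined_periods_are_skipped(self):
        up = {4: 80.0, 3: 20.0}  # one period per side is enough
        assert eo_statistic(up) == pytest.approx(60.0)
        assert np.isnan(eo_statistic({4: 80.0}))  # no down period at all

    def test_group_mean_equals_eo_of_mean_profiles(self):
        # E-O is linear in the per-period up%, so averaging commutes with it
        rng = np.random.default_rng(1)
        profiles = rng.uniform(0, 100, size=(24, 10))
        periods = list(range(3, 13))
        eos = [eo_statistic(dict(zip(periods, row))) for row in profiles]
        mean_profile = dict(zip(periods, profiles.mean(axis=0)))
        assert np.mean(eos) == pytest.approx(eo_statistic(mean_profile))


def _synthetic_results(n_wells=144, inactive_wells=(0,)):
    """A hand-built detection results table: periods 1..12, 10 intervals per
    period; listed wells never move, the rest move every interval and sit up
    in even periods, down in odd."""
    rows = []
    for w in range(n_wells):
        plate, rest = divmod(w, 48)
        row, col = divmod(rest, 12)
        fp = 0
        for period in range(1, 13):
            stim = "none" if period <= 2 else ("down" if period % 2 else "up")
            for _ in range(10):
                inactive = w in inactive_wells
                up = np.nan if inactive or period <= 2 else float(period % 2 == 0)
                rows.append(
                    dict(
                        plate=plate, row=row, col=col, frame_pair=fp,
                        period=period, stimulus=stim,
                        area=0 if inactive else 40,
                        centroid_x=np.nan if inactive else 18.0,
                        centroid_y=np.nan if inactive else 18.0,
                        move=0 if inactive else 1, up=up,
                    )
                )
                fp += 1
    return pd.DataFrame(rows)


class TestScoreLarvae:
    def test_immotile_larvae_have_zero_activity_and_invalid_eo(self):
        res = _synthetic_results(n_wells=12, inactive_wells=range(12))
        scores = score_larvae(res)
        assert (scores.activity_pct == 0).all()
        assert (~scores.eo_valid).all()
        assert scores.eo.isna().all()

    def test_one_inactive_larva_leaves_143_valid_of_144(self):
        scores = score_larvae(_synthetic_results(144, inactive_wells=(7,)))
        assert len(scores) == 144
        assert int(scores.eo_valid.sum()) == 143

    def test_active_followers_score_perfect_eo(self):
        scores = score_larvae(_synthetic_results(12, inactive_wells=()))
        assert scores.eo.to_numpy() == pytest.approx(np.full(12, 100.0))
        assert scores.activity_pct.to_numpy() == pytest.approx(np.full(12, 100.0))

    def test_headline_activity_is_the_first_period(self):
        res = _synthetic_results(2, inactive_wells=())
        # silence movement outside period 1 for one well
        mask = (res.plate == 0) & (res.row == 0) & (res.col == 1) & (res.period > 1)
        res.loc[mask, "move"] = 0
        scores = score_larvae(res).set_index("col")
        assert scores.loc[1, "activity_first_pct"] == 100.0
        assert scores.loc[1, "activity_pct"] == pytest.approx(100.0 / 12)

    def test_activity_floor_is_configurable(self):
        res = _synthetic_results(2, inactive_wells=())
        mask = (res.plate == 0) & (res.row == 0) & (res.col == 1) & (res.period > 1)
        res.loc[mask, "move"] = 0  # activity 8.3%
        assert score_larvae(res, activity_floor=5.0).eo_valid.all()
        assert not score_larvae(res, activity_floor=10.0).set_index("col").loc[1, "eo_valid"]


class TestPipelineRecovery:
    """Parameter recovery on the rendered gain-ladder experiment."""

    def test_measured_activity_within_three_binomial_se_of_p_move(self, gain_ladder):
        p = gain_ladder.p_move
        scores = gain_ladder.scores
        n_draws = scores.n_intervals.sum()
        se = 100.0 * np.sqrt(p * (1 - p) / n_draws)
        assert abs(scores.activity_pct.mean() - 100.0 * p) < 3 * se

    def test_eo_is_strictly_monotone_in_gain(self, gain_ladder):
        means = gain_ladder.scores.groupby("gain").eo.mean()
        rho = spearmanr(means.index, means.to_numpy()).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_gain_group_mean_eo_is_near_zero(self, gain_ladder):
        sub = gain_ladder.scores[gain_ladder.scores.gain == 0.0]
        se = sub.eo.std(ddof=1) / np.sqrt(len(sub))
        assert abs(sub.eo.mean()) < 3 * se

    def test_full_gain_group_mean_eo_exceeds_fifty(self, gain_ladder):
        sub = gain_ladder.scores[gain_ladder.scores.gain == 1.0]
        assert sub.eo.mean() > 50.0

    def test_higher_gain_beats_zero_gain_on_paired_seeds(self, gain_ladder):
        scores = gain_ladder.scores
        assert (
            scores[scores.gain == 0.75].eo.mean()
            > scores[scores.gain == 0.0].eo.mean()
        )


class TestSummarizeGroup:
    def _scores(self, activities, eos=None, group="g"):
        n = len(activities)
        eos = eos if eos is not None else activities
        return pd.DataFrame(
            dict(
                plate=0, row=0, col=range(n), n_intervals=100,
                activity_pct=activities, activity_first_pct=activities,
                eo=eos, eo_valid=[np.isfinite(e) for e in eos], group=group,
            )
        )

    def test_mean_and_sem_of_two_larvae(self):
        out = summarize_group(self._scores([40.0, 60.0]))
        assert out.activity_mean[0] == 50.0
        assert out.activity_sem[0] == pytest.approx(10.0)  # SD 14.142 / sqrt(2)

    def test_single_larva_has_undefined_sem(self):
        out = summarize_group(self._scores([40.0]))
        assert np.isnan(out.activity_sem[0])

    def test_identical_larvae_have_zero_sem(self):
        out = summarize_group(self._scores([55.0] * 6))
        assert out.activity_sem[0] == 0.0

    def test_eo_stats_count_only_valid_larvae(self):
        out = summarize_group(self._scores([50.0] * 4, [10.0, 20.0, np.nan, np.nan]))
        assert out.n[0] == 4 and out.n_eo[0] == 2
        assert out.eo_mean[0] == pytest.approx(15.0)

    def test_empty_group_raises(self):
        with pytest.raises(ScoreError):
            summarize_group(self._scores([]).iloc[0:0])

    def test_row_means_average_rows_of_twelve(self, gain_ladder):
        rm = row_means(gain_ladder.scores)
        assert len(rm) == 10
        assert (rm.n == 12).all()
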