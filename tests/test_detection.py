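"""Channel selection, frame differencing, per-well measurement, and the
full detector against simulator ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plateomr import (
    DetectionConfig,
    DetectionError,
    PlateLayout,
    StimulusSpec,
    WellMeasurement,
    WellRegion,
    background_subtract,
    classify_up,
    frame_difference,
    measure_well,
    median_background,
    run_detection,
    select_channel,
)

from tests.helpers import SINGLE_WELL, blob_diff_image, min_foreground_intensity, min_move_area


def _stimulus_frame(bg, line, size=24, line_rows=range(4, 8)):
    f = np.empty((size, size, 3), dtype=np.uint8)
    f[:] = np.asarray(bg, np.uint8)
    f[list(line_rows)] = np.asarray(line, np.uint8)
    return f


class TestSelectChannel:
    def test_red_lines_on_gray_pick_red(self):
        # |255-191| = 64 beats |0-191| = 191 in green and blue
        f = _stimulus_frame((191, 191, 191), (255, 0, 0))
        assert select_channel([f], StimulusSpec()) == 0

    def test_blue_lines_on_gray_pick_blue(self):
        f = _stimulus_frame((191, 191, 191), (0, 0, 255))
        spec = StimulusSpec(line_color=(0, 0, 255))
        assert select_channel([f], spec) == 2

    def test_grayscale_stimulus_ties_break_to_red(self):
        f = _stimulus_frame((191, 191, 191), (100, 100, 100))
        assert select_channel([f], StimulusSpec()) == 0

    def test_blank_frame_falls_back(self):
        f = _stimulus_frame((191, 191, 191), (191, 191, 191))
        assert select_channel([f], StimulusSpec(), fallback=1) == 1


class TestFrameDifference:
    def test_identical_frames_give_all_zero(self):
        f = np.full((8, 8), 100, np.uint8)
        assert not frame_difference(f, f).any()

    def test_difference_magnitude(self):
        a = np.full((4, 4), 191, np.uint8)
        b = np.full((4, 4), 60, np.uint8)
        assert np.all(frame_difference(a, b) == 131)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DetectionError):
            frame_difference(np.zeros((4, 4)), np.zeros((4, 5)))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_difference_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        b = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        assert np.array_equal(frame_difference(a, b), frame_difference(b, a))


class TestBackgroundSubtract:
    def test_frame_equal_to_background_gives_zero(self):
        f = np.full((6, 6), 120, np.uint8)
        assert not background_subtract(f, f.copy()).any()

    def test_median_of_constant_series_is_that_constant(self):
        frames = [np.full((5, 5), 77, np.uint8)] * 5
        assert np.all(median_background(frames) == 77)

    def test_static_larva_detected_against_reference_background(self):
        bg = np.full((40, 40), 191, np.uint8)
        frame = bg.copy()
        frame[15:21, 15:21] = 60  # a larva that never moves
        diff = background_subtract(frame, bg)
        m = measure_well(diff, SINGLE_WELL, DetectionConfig())
        assert m.move == 1 and m.area == 36


class TestMeasureWell:
    def test_twenty_pixel_blob_is_movement(self):
        m = measure_well(blob_diff_image(20), SINGLE_WELL, DetectionConfig())
        assert m.area == 20 and m.move == 1

    def test_nineteen_pixel_blob_is_not_movement(self):
        m = measure_well(blob_diff_image(19), SINGLE_WELL, DetectionConfig())
        assert m.area == 19 and m.move == 0

    def test_intensity_below_threshold_is_background(self):
        m = measure_well(blob_diff_image(100, intensity=24), SINGLE_WELL, DetectionConfig())
        assert m.area == 0 and m.move == 0 and m.centroid is None

    def test_intensity_at_threshold_is_foreground(self):
        m = measure_well(blob_diff_image(100, intensity=25), SINGLE_WELL, DetectionConfig())
        assert m.area == 100 and m.move == 1

    def test_sweeps_recover_the_operational_constants(self):
        assert min_move_area() == 20
        assert min_foreground_intensity() == 25

    def test_centroid_is_mean_of_pixel_centers(self):
        img = np.zeros((40, 40), np.uint8)
        img[10, 10] = 255
        img[10, 12] = 255
        m = measure_well(img, SINGLE_WELL, DetectionConfig(move_area_min=1))
        assert m.centroid == (11.5, 10.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_matches_brute_force_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        region = WellRegion(plate=0, row=0, col=0, bbox=(3, 2, 17, 19))
        cfg = DetectionConfig(diff_threshold=25, move_area_min=20)
        m = measure_well(img, region, cfg)
        # independent oracle: explicit per-pixel loop
        xs, ys = [], []
        for y in range(2, 19):
            for x in range(3, 17):
                if img[y, x] >= 25:
                    xs.append(x + 0.5)
                    ys.append(y + 0.5)
        assert m.area == len(xs)
        assert m.move == int(len(xs) >= 20)
        if xs:
            assert m.centroid == pytest.approx((np.mean(xs), np.mean(ys)))
        else:
            assert m.centroid is None

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_raising_thresholds_never_increases_move_counts(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 80, (40, 40), dtype=np.uint8)
        moves = [
            measure_well(img, SINGLE_WELL, DetectionConfig(diff_threshold=thr)).move
            for thr in (10, 25, 40, 60)
        ]
        assert moves == sorted(moves, reverse=True)
        moves = [
            measure_well(img, SINGLE_WELL, DetectionConfig(move_area_min=amin)).move
            for amin in (1, 20, 100, 500)
        ]
        assert moves == sorted(moves, reverse=True)


class TestClassifyUp:
    region = WellRegion(plate=0, row=0, col=0, bbox=(0, 0, 100, 100))

    def _measurement(self, centroid):
        return WellMeasurement(
            plate=0, row=0, col=0, frame_pair=None, area=25, centroid=centroid, move=1
        )

    def test_centroid_above_center_is_up(self):
        assert classify_up(self._measurement((50.0, 10.0)), self.region) == 1

    def test_centroid_below_center_is_down(self):
        assert classify_up(self._measurement((50.0, 90.0)), self.region) == 0

    def test_exact_center_ties_to_down(self):
        assert classify_up(self._measurement((50.0, 50.0)), self.region) == 0

    def test_no_centroid_is_missing(self):
        m = WellMeasurement(
            plate=0, row=0, col=0, frame_pair=None, area=0, centroid=None, move=0
        )
        assert classify_up(m, self.region) is None


class TestRunDetection:
    layout = PlateLayout(1, 1, 4, row_outlines=((0, 0, 40, 10),))

    def test_two_frames_give_one_row_per_well(self):
        frames = [np.zeros((10, 40, 3), np.uint8)] * 2
        df = run_detection(frames, self.layout)
        assert len(df) == 4
        assert set(zip(df.plate, df.row, df.col)) == {(0, 0, c) for c in range(4)}

    def test_static_series_scores_no_movement(self):
        frames = [np.full((10, 40, 3), 191, np.uint8)] * 5
        df = run_detection(frames, self.layout)
        assert len(df) == 16
        assert (df.move == 0).all()
        assert df.up.isna().all()

    def test_single_frame_raises(self):
        with pytest.raises(DetectionError):
            run_detection([np.zeros((10, 40, 3), np.uint8)], self.layout)

    def test_background_mode_detects_static_larvae(self):
        bg = np.full((10, 40, 3), 191, np.uint8)
        frame = bg.copy()
        frame[2:8, 1:9] = 60  # static larva in well 0
        frames = [frame] * 3
        cfg = DetectionConfig(mode="background", channel="red", move_area_min=20)
        df = run_detection(frames, self.layout, config=cfg, background=bg[..., 0])
        well0 = df[df.col == 0]
        assert (well0.move == 1).all()
        subtractive = run_detection(frames, self.layout)
        assert (subtractive.move == 0).all()

    def test_move_flags_match_simulator_ground_truth_exactly(self, gain_ladder):
        truth = gain_ladder.exp.truth_table()
        tt = truth[truth.frame > 0].copy()
        tt["frame_pair"] = tt["frame"] - 1
        merged = gain_ladder.results.merge(
            tt[["plate", "row", "col", "frame_pair", "moved"]],
            on=["plate", "row", "col", "frame_pair"],
            validate="one_to_one",
        )
        assert len(merged) == len(gain_ladder.results)
        assert (merged.move == merged.moved).all()

    def test_rows_carry_the_period_of_the_later_frame(self, gain_ladder):
        df = gain_ladder.results
        sched = gain_ladder.schedule
        sample = df[df.col == 0].head(300)
        for fp, period in zip(sample.frame_pair, sample.period):
            assert sched.period_of_frame(fp + 1)[0] == period
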