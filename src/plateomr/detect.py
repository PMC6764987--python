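"""Image-analysis core: channel selection, frame differencing, thresholding,
and per-well measurement of moving-larva area and centroid.

The subtractive mode takes the absolute difference of each consecutive frame
pair in one color channel, which suppresses static structure (well walls,
the line pattern wherever its intensity matches the background in that
channel) and highlights displaced larvae.  Within each well region, pixels
at or above the difference threshold are counted; a well "moved" in an
interval when that area reaches the move cutoff, and the unweighted centroid
of the suprathreshold pixels locates the larva in the upper or lower half of
the well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import PlateLayout, WellRegion, well_center
from .schedule import PeriodSchedule, StimulusSpec

log = logging.getLogger(__name__)

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


class DetectionError(ValueError):
    """Invalid detection inputs or configuration."""


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and mode of the detector.

    ``diff_threshold``: minimum 8-bit difference intensity counted as
    foreground (threshold band 25-255).  ``move_area_min``: minimum
    suprathreshold area in pixels for a well to score as moved (20 px).
    """

    diff_threshold: int = 25
    move_area_min: int = 20
    channel: str | int = "auto"
    mode: str = "subtractive"

    def __post_init__(self) -> None:
        if not 0 < self.diff_threshold <= 255:
            raise DetectionError("diff_threshold must be in (0, 255]")
        if self.move_area_min < 1:
            raise DetectionError("move_area_min must be >= 1")
        if self.mode not in ("subtractive", "background"):
            raise DetectionError(f"unknown mode {self.mode!r}")
        ch = self.channel
        if isinstance(ch, str) and ch != "auto" and ch not in _CHANNELS:
            raise DetectionError(f"unknown channel {ch!r}")
        if isinstance(ch, int) and ch not in (0, 1, 2):
            raise DetectionError(f"channel index must be 0..2, got {ch}")

    def resolve_channel(self, frames=None, stimulus: StimulusSpec | None = None) -> int:
        if isinstance(self.channel, int):
            return self.channel
        if self.channel in _CHANNELS:
            return _CHANNELS[self.channel]
        if frames is None:
            return 0
        return select_channel(frames, stimulus)


@dataclass(frozen=True)
class WellMeasurement:
    """Measured values for one well over one frame pair: thresholded area,
    centroid of the suprathreshold pixels (None when the area is zero),
    the move flag, and the up flag (None when no centroid is defined)."""

    plate: int
    row: int
    col: int
    frame_pair: tuple[int, int] | None
    area: int
    centroid: tuple[float, float] | None
    move: int
    up: int | None = None


def select_channel(
    frames: Iterable[np.ndarray],
    stimulus: StimulusSpec | None = None,
    *,
    bg_tol: float = 30.0,
    fallback: int = 0,
) -> int:
    """Pick the color channel in which the stimulus lines and the background
    have the most similar intensity.

    Pixels deviating from the nominal background color by more than
    ``bg_tol`` (Euclidean RGB distance) are treated as stimulus pixels; the
    channel minimizing |mean stimulus intensity - mean background intensity|
    wins, ties broken in R, G, B order.  Falls back to ``fallback`` when no
    stimulus pixels are found (e.g. blank-background frames).
    """
    spec = stimulus or StimulusSpec()
    bg = np.asarray(spec.background_color, dtype=float)
    line_sum = np.zeros(3)
    line_n = 0
    bg_sum = np.zeros(3)
    bg_n = 0
    for frame in frames:
        if frame.ndim != 3 or frame.shape[2] < 3:
            raise DetectionError("select_channel expects RGB frames")
        flat = frame[..., :3].reshape(-1, 3).astype(float)
        dist2 = ((flat - bg) ** 2).sum(axis=1)
        is_line = dist2 > bg_tol * bg_tol
        line_sum += flat[is_line].sum(axis=0)
        line_n += int(is_line.sum())
        bg_sum += flat[~is_line].sum(axis=0)
        bg_n += int((~is_line).sum())
    if line_n == 0 or bg_n == 0:
        return fallback
    contrast = np.abs(line_sum / line_n - bg_sum / bg_n)
    return int(np.argmin(contrast))  # argmin keeps the first (R, G, B) on ties


def _as_channel(frame: np.ndarray, channel: int | None) -> np.ndarray:
    if frame.ndim == 3:
        if channel is None:
            raise DetectionError("a channel index is required for RGB frames")
        return frame[..., channel]
    return frame


def frame_difference(
    frame_i: np.ndarray, frame_j: np.ndarray, channel: int | None = None
) -> np.ndarray:
    """Absolute per-pixel difference of two frames in one channel, 8-bit.

    The unsigned difference is symmetric, so a larva leaving a pixel and a
    larva arriving at it are highlighted equally.
    """
    a = _as_channel(np.asarray(frame_i), channel)
    b = _as_channel(np.asarray(frame_j), channel)
    if a.shape != b.shape:
        raise DetectionError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return np.abs(a.astype(np.int16) - b.astype(np.int16)).astype(np.uint8)


def median_background(
    frames: Sequence[np.ndarray], channel: int | None = None, max_frames: int = 101
) -> np.ndarray:
    """Per-pixel median of (a subsample of) the series in one channel,
    usable as a static-background reference."""
    n = len(frames)
    if n == 0:
        raise DetectionError("cannot compute a background from zero frames")
    idx = np.unique(np.linspace(0, n - 1, min(n, max_frames)).astype(int))
    stack = np.stack([_as_channel(np.asarray(frames[i]), channel) for i in idx])
    return np.median(stack, axis=0).astype(np.uint8)


def background_subtract(
    frame: np.ndarray, background: np.ndarray, channel: int | None = None
) -> np.ndarray:
    """Absolute difference of one frame against a background reference.

    Unlike the subtractive mode this also detects larvae that do not move,
    as long as they differ from the background."""
    return frame_difference(frame, background, channel=channel) if frame.ndim == 3 else \
        np.abs(_as_channel(frame, channel).astype(np.int16)
               - background.astype(np.int16)).astype(np.uint8)


def measure_well(
    diff: np.ndarray, region: WellRegion, config: DetectionConfig | None = None
) -> WellMeasurement:
    """Thresholded area, centroid, and move flag of one well region in a
    difference image.

    Area counts pixels with intensity >= ``diff_threshold`` inside the region
    (restricted to the circular well when the region uses a circular mask);
    the centroid is the unweighted mean pixel-center position of those
    pixels, in image coordinates; ``move`` is 1 iff area >= ``move_area_min``.
    """
    config = config or DetectionConfig()
    x0, y0, x1, y1 = region.bbox
    if diff.ndim != 2:
        raise DetectionError("measure_well expects a single-channel image")
    if y1 > diff.shape[0] or x1 > diff.shape[1]:
        raise DetectionError(f"region {region.bbox} exceeds image {diff.shape}")
    sub = diff[y0:y1, x0:x1]
    fg = sub >= config.diff_threshold
    if region.mask_shape == "circle":
        fg = fg & region.pixel_mask()
    area = int(fg.sum())
    if area == 0:
        centroid = None
    else:
        ys, xs = np.nonzero(fg)
        centroid = (x0 + float(xs.mean()) + 0.5, y0 + float(ys.mean()) + 0.5)
    return WellMeasurement(
        plate=region.plate,
        row=region.row,
        col=region.col,
        frame_pair=None,
        area=area,
        centroid=centroid,
        move=int(area >= config.move_area_min),
    )


def classify_up(measurement: WellMeasurement, region: WellRegion) -> int | None:
    """1 when the larval centroid is above the well center (smaller y),
    0 when below or exactly at the center, None when no centroid exists."""
    if measurement.centroid is None:
        return None
    _, cy = measurement.centroid
    _, wy = well_center(region)
    return 1 if cy < wy else 0


def run_detection(
    frames,
    layout: PlateLayout,
    schedule: PeriodSchedule | None = None,
    config: DetectionConfig | None = None,
    *,
    stimulus: StimulusSpec | None = None,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the detector over a whole frame series.

    ``frames`` may be any iterable of RGB (or single-channel) frames; in
    subtractive mode one output row is produced per (well, consecutive frame
    pair), in background mode one row per (well, frame).  Rows carry the
    period id and stimulus direction of the frame on which the movement is
    observed (the later frame of a pair).  Output columns: plate, row, col,
    frame_pair, period, stimulus, area, centroid_x, centroid_y, move, up.
    """
    config = config or DetectionConfig()
    wells = layout.wells()
    centers_y = np.array([well_center(w)[1] for w in wells])

    if config.mode == "background":
        if not isinstance(frames, Sequence):
            frames = list(frames)
        if background is None:
            channel = config.resolve_channel(frames[:1], stimulus)
            background = median_background(frames, channel)
        else:
            channel = config.resolve_channel(frames[:1], stimulus)

    cols: dict[str, list] = {k: [] for k in (
        "plate", "row", "col", "frame_pair", "period", "stimulus",
        "area", "centroid_x", "centroid_y", "move", "up",
    )}

    def emit(diff: np.ndarray, pair_index: int, observed_frame: int) -> None:
        if schedule is not None:
            pid, stim = schedule.period_of_frame(observed_frame)
        else:
            pid, stim = -1, "none"
        for w_i, region in enumerate(wells):
            m = measure_well(diff, region, config)
            up = None
            if m.centroid is not None:
                up = 1 if m.centroid[1] < centers_y[w_i] else 0
            cols["plate"].append(region.plate)
            cols["row"].append(region.row)
            cols["col"].append(region.col)
            cols["frame_pair"].append(pair_index)
            cols["period"].append(pid)
            cols["stimulus"].append(stim)
            cols["area"].append(m.area)
            cols["centroid_x"].append(np.nan if m.centroid is None else m.centroid[0])
            cols["centroid_y"].append(np.nan if m.centroid is None else m.centroid[1])
            cols["move"].append(m.move)
            cols["up"].append(np.nan if up is None else up)

    it = iter(frames)
    if config.mode == "background":
        for i, frame in enumerate(it):
            diff = background_subtract(np.asarray(frame), background, channel)
            emit(diff, i, i)
        n_units = "frames"
    else:
        try:
            prev = np.asarray(next(it))
        except StopIteration:
            raise DetectionError("subtractive mode needs at least 2 frames")
        channel = config.resolve_channel([prev] if prev.ndim == 3 else None, stimulus)
        i = 0
        for frame in it:
            frame = np.asarray(frame)
            try:
                diff = frame_difference(prev, frame, channel if frame.ndim == 3 else None)
            except DetectionError as exc:
                raise DetectionError(f"frame pair ({i}, {i + 1}): {exc}") from exc
            emit(diff, i, i + 1)
            prev = frame
            i += 1
        if i == 0:
            raise DetectionError("subtractive mode needs at least 2 frames")
        n_units = "frame pairs"

    df = pd.DataFrame(cols)
    log.info(
        "detection: %d wells x %d %s -> %d rows",
        len(wells), df["frame_pair"].nunique(), n_units, len(df),
    )
    return df
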