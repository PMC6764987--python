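"""Experiment timeline and stimulus geometry.

A recording is divided into fixed-length *periods* (10 minutes by default).
The default two-hour assay starts with two blank periods (plain gray
background) followed by ten periods of moving red lines that alternate
direction: odd-numbered periods move the lines *down* the image, even ones
*up*.  Frames are acquired at a fixed interval (6 s by default), so each
default period spans exactly 100 frames.

A 1-hour acclimation precedes the recording; if acclimation frames are
present in an image series they are tagged period 0 and excluded from all
behavioral scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Direction = str  # "none" | "down" | "up"

_DIRECTIONS = ("none", "down", "up")


class ScheduleError(ValueError):
    """Invalid schedule or out-of-range frame index."""


def default_periods(n_blank: int = 2, n_stimulus: int = 10) -> tuple[tuple[int, Direction], ...]:
    """Blank periods 1..n_blank, then alternating stimulus periods starting
    with "down" (so with two blank periods, odd periods are "down" and even
    periods "up")."""
    periods: list[tuple[int, Direction]] = [(i + 1, "none") for i in range(n_blank)]
    for k in range(n_stimulus):
        pid = n_blank + k + 1
        periods.append((pid, "down" if k % 2 == 0 else "up"))
    return tuple(periods)


@dataclass(frozen=True)
class PeriodSchedule:
    """Recording timeline: frame interval, period length, and the ordered
    period list with each period's stimulus direction.

    ``acclimation`` is the pre-recording acclimation time in seconds (not
    normally part of the frame series); ``acclimation_frames`` says how many
    *leading frames of the series* belong to the acclimation and should be
    tagged period 0.
    """

    frame_interval: float = 6.0
    period_length: float = 600.0
    periods: tuple[tuple[int, Direction], ...] = field(default_factory=default_periods)
    acclimation: float = 3600.0
    acclimation_frames: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.period_length <= 0:
            raise ScheduleError("frame_interval and period_length must be > 0")
        fpp = self.period_length / self.frame_interval
        if abs(fpp - round(fpp)) > 1e-9:
            raise ScheduleError(
                f"period_length {self.period_length}s is not divisible by "
                f"frame_interval {self.frame_interval}s"
            )
        norm = []
        seen = set()
        for pid, stim in self.periods:
            if stim not in _DIRECTIONS:
                raise ScheduleError(f"unknown stimulus {stim!r} in period {pid}")
            if pid in seen:
                raise ScheduleError(f"duplicate period id {pid}")
            seen.add(pid)
            norm.append((int(pid), stim))
        object.__setattr__(self, "periods", tuple(norm))
        if self.acclimation_frames < 0:
            raise ScheduleError("acclimation_frames must be >= 0")

    @property
    def frames_per_period(self) -> int:
        return int(round(self.period_length / self.frame_interval))

    @property
    def n_frames(self) -> int:
        """Total number of frames in the series (acclimation included)."""
        return self.acclimation_frames + len(self.periods) * self.frames_per_period

    @property
    def recording_length(self) -> float:
        """Recorded (post-acclimation) duration in seconds."""
        return len(self.periods) * self.period_length

    def period_of_frame(self, frame_index: int) -> tuple[int, Direction]:
        """Map a frame index to its (period_id, stimulus direction).

        Acclimation frames map to (0, "none").  Raises for indices outside
        the recording.
        """
        if frame_index < 0 or frame_index >= self.n_frames:
            raise ScheduleError(
                f"frame {frame_index} outside recording of {self.n_frames} frames"
            )
        if frame_index < self.acclimation_frames:
            return (0, "none")
        k = (frame_index - self.acclimation_frames) // self.frames_per_period
        return self.periods[k]

    def time_of_frame(self, frame_index: int) -> float:
        """Seconds since the start of the recording (acclimation negative)."""
        return (frame_index - self.acclimation_frames) * self.frame_interval

    def stimulus_periods(self, direction: Direction) -> tuple[int, ...]:
        return tuple(pid for pid, stim in self.periods if stim == direction)

    @property
    def up_periods(self) -> tuple[int, ...]:
        """Periods with lines moving up (periods 4, 6, 8, 10, 12 by default)."""
        return self.stimulus_periods("up")

    @property
    def down_periods(self) -> tuple[int, ...]:
        """Periods with lines moving down (periods 3, 5, 7, 9, 11 by default)."""
        return self.stimulus_periods("down")

    def to_dict(self) -> dict:
        return {
            "frame_interval": self.frame_interval,
            "period_length": self.period_length,
            "periods": [[pid, stim] for pid, stim in self.periods],
            "acclimation": self.acclimation,
            "acclimation_frames": self.acclimation_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PeriodSchedule":
        kw = dict(d)
        if "periods" in kw:
            kw["periods"] = tuple((int(p), s) for p, s in kw["periods"])
        elif "n_blank" in kw or "n_stimulus" in kw:
            kw["periods"] = default_periods(
                int(kw.pop("n_blank", 2)), int(kw.pop("n_stimulus", 10))
            )
        return cls(**kw)


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and nominal colors of the moving-line stimulus.

    Horizontal red lines of 1 mm thickness, spaced 7 mm apart edge to edge
    (pattern pitch 8 mm), moving at 7 mm per 8 s.  Colors are the nominal
    projected RGB values; the renderer applies its own camera model for the
    colors actually observed in acquired images.
    """

    line_thickness: float = 1.0  # mm
    line_gap: float = 7.0  # mm, edge-to-edge
    speed: float = 7.0 / 8.0  # mm per second
    line_color: tuple[int, int, int] = (255, 0, 0)
    background_color: tuple[int, int, int] = (191, 191, 191)

    def __post_init__(self) -> None:
        if min(self.line_thickness, self.line_gap, self.speed) <= 0:
            raise ScheduleError("line thickness, gap, and speed must be > 0")
        for c in (*self.line_color, *self.background_color):
            if not 0 <= c <= 255:
                raise ScheduleError("colors must be within [0, 255]")
        object.__setattr__(self, "line_color", tuple(int(c) for c in self.line_color))
        object.__setattr__(
            self, "background_color", tuple(int(c) for c in self.background_color)
        )

    @property
    def pitch(self) -> float:
        """Spatial period of the line pattern, mm."""
        return self.line_thickness + self.line_gap

    @property
    def temporal_period(self) -> float:
        """Time for the pattern to advance one pitch, seconds."""
        return self.pitch / self.speed

    def to_dict(self) -> dict:
        return {
            "line_thickness": self.line_thickness,
            "line_gap": self.line_gap,
            "speed": self.speed,
            "line_color": list(self.line_color),
            "background_color": list(self.background_color),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        kw = dict(d)
        for key in ("line_color", "background_color"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def stimulus_offset(spec: StimulusSpec, t: float, direction: Direction) -> float:
    """Signed displacement (mm) of the line pattern at time ``t``.

    Positive offsets move the pattern toward larger y ("down" in image
    coordinates); the magnitude is ``speed * t`` wrapped modulo the pattern
    pitch.  A "none" direction leaves the pattern at rest.
    """
    if t < 0:
        raise ScheduleError(f"t must be >= 0, got {t}")
    if direction not in _DIRECTIONS:
        raise ScheduleError(f"unknown direction {direction!r}")
    if direction == "none":
        return 0.0
    mag = (spec.speed * t) % spec.pitch
    return mag if direction == "down" else -mag
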