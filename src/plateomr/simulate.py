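"""Agent-based synthetic plate: stochastic larvae in wells plus a renderer.

Each larva is a rigid dark ellipse confined to the circular well of a
shallow-well plate.  Per 6-second frame interval it moves with probability
``p_move``; the displacement direction is a mixture of a uniform random unit
vector (weight ``1 - g``) and the current stimulus direction (weight ``g``,
the optomotor gain).  ``g = 0`` models a blind larva, ``g = 1`` a perfect
stimulus follower.  The renderer draws the gray background, the moving line
pattern as seen by the camera, and the larvae, giving image series on which
the full detection pipeline can be validated against known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .geometry import PlateLayout, WellRegion, WELL_DIAMETER_MM
from .schedule import Direction, PeriodSchedule, StimulusSpec, stimulus_offset

log = logging.getLogger(__name__)

WELL_RADIUS_MM = WELL_DIAMETER_MM / 2.0

_DIRVEC = {"down": (0.0, 1.0), "up": (0.0, -1.0)}


class RenderError(ValueError):
    """A larva or stimulus cannot be drawn inside the image."""


@dataclass(frozen=True)
class LarvaParams:
    """Behavioral and rendering parameters of one simulated larva.

    ``step_length`` is a free simulator parameter (mm displaced per moving
    interval); ``body_axes`` are the ellipse semi-axes in mm, sized for a
    5-dpf larva of about 4 mm length.
    """

    p_move: float = 0.5
    optomotor_gain: float = 0.0
    step_length: float = 1.0
    body_axes: tuple[float, float] = (2.0, 0.5)
    body_intensity: tuple[int, int, int] = (60, 60, 60)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_move <= 1.0:
            raise ValueError(f"p_move must be in [0, 1], got {self.p_move}")
        if not 0.0 <= self.optomotor_gain <= 1.0:
            raise ValueError(f"optomotor_gain must be in [0, 1], got {self.optomotor_gain}")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        object.__setattr__(self, "body_axes", tuple(float(a) for a in self.body_axes))
        object.__setattr__(
            self, "body_intensity", tuple(int(c) for c in self.body_intensity)
        )

    def to_dict(self) -> dict:
        return {
            "p_move": self.p_move,
            "optomotor_gain": self.optomotor_gain,
            "step_length": self.step_length,
            "body_axes": list(self.body_axes),
            "body_intensity": list(self.body_intensity),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LarvaParams":
        kw = dict(d)
        for key in ("body_axes", "body_intensity"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


#: Treatment-like presets.  "untreated" reproduces healthy larvae (moderate
#: activity, strong stimulus following); "immotile" the anesthetized/sedated
#: phenotype; "hyperactive" elevated activity; "blind" normal activity with
#: no visual response.
PRESETS: dict[str, LarvaParams] = {
    "untreated": LarvaParams(p_move=0.5, optomotor_gain=0.8),
    "immotile": LarvaParams(p_move=0.0, optomotor_gain=0.0),
    "hyperactive": LarvaParams(p_move=0.9, optomotor_gain=0.8),
    "blind": LarvaParams(p_move=0.5, optomotor_gain=0.0),
}


@dataclass
class LarvaState:
    """Position (mm, relative to the well center, y down) and heading of one
    larva inside its well."""

    region: WellRegion
    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0


@dataclass(frozen=True)
class RenderSpec:
    """How simulated frames are rasterized.

    ``pixels_per_mm`` defaults to a desk-scale 4 px/mm (the original rig
    resolves about 20.7 px/mm); ``line_rgb`` is the camera-observed color of
    the projected red lines — the projector brightness is matched to the
    camera so the red channel of the lines stays close to the background
    (here 210 vs 191, i.e. below the detection threshold), while green and
    blue carry the visible line contrast.
    """

    pixels_per_mm: float = 4.0
    noise_sd: float = 0.0
    line_rgb: tuple[int, int, int] = (210, 60, 60)
    well_diameter_mm: float = WELL_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "line_rgb", tuple(int(c) for c in self.line_rgb))

    def to_dict(self) -> dict:
        return {
            "pixels_per_mm": self.pixels_per_mm,
            "noise_sd": self.noise_sd,
            "line_rgb": list(self.line_rgb),
            "well_diameter_mm": self.well_diameter_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RenderSpec":
        kw = dict(d)
        if "line_rgb" in kw:
            kw["line_rgb"] = tuple(kw["line_rgb"])
        return cls(**kw)


def _step_direction(gain: float, stimulus: Direction, rng: np.random.Generator) -> np.ndarray:
    """Mixture distribution over step directions: with probability ``gain``
    the step is exactly along the stimulus, otherwise uniform random (always
    uniform when there is no stimulus)."""
    d = _DIRVEC.get(stimulus)
    if d is not None and gain > 0.0 and rng.random() < gain:
        return np.asarray(d, dtype=float)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([math.cos(ang), math.sin(ang)])


def step_larva(
    state: LarvaState,
    params: LarvaParams,
    stimulus: Direction,
    rng: np.random.Generator,
    *,
    well_radius_mm: float = WELL_RADIUS_MM,
) -> tuple[LarvaState, bool]:
    """Advance one larva by one frame interval.

    With probability ``p_move`` the larva displaces by ``step_length`` in a
    direction mixing a uniform random vector (weight 1 - g) with the stimulus
    direction (weight g).  Directions that would leave the swimmable disc
    (well radius minus body semi-major axis) are re-drawn; when the direction
    distribution is too concentrated to stay inside (e.g. g = 1 pressing
    against the wall) the larva instead slides one step length along the
    wall, in the direction of the step's tangential component — the
    wall-following behavior familiar from larvae in circular arenas.
    Returns the new state and whether the larva moved.
    """
    if rng.random() >= params.p_move:
        return state, False
    r_max = max(well_radius_mm - params.body_axes[0], 0.05 * well_radius_mm)
    pos = np.array([state.x, state.y])
    new = None
    v = np.array([1.0, 0.0])
    for _ in range(16):
        v = _step_direction(params.optomotor_gain, stimulus, rng)
        cand = pos + params.step_length * v
        if cand @ cand <= r_max * r_max:
            new = cand
            break
    if new is None:  # pinned against the wall: slide along it
        rho = math.hypot(pos[0], pos[1])
        phi = math.atan2(pos[1], pos[0]) if rho > 1e-9 else math.atan2(v[1], v[0])
        tangential = -v[0] * math.sin(phi) + v[1] * math.cos(phi)
        if abs(tangential) > 1e-9:
            sign = 1.0 if tangential > 0 else -1.0
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        phi2 = phi + sign * params.step_length / r_max
        new = np.array([r_max * math.cos(phi2), r_max * math.sin(phi2)])
    disp = new - pos
    dn = math.hypot(disp[0], disp[1])
    heading = math.atan2(disp[1], disp[0]) if dn > 1e-12 else state.heading
    moved = dn > 1e-9
    return replace(state, x=float(new[0]), y=float(new[1]), heading=heading), moved


def _initial_state(
    region: WellRegion, params: LarvaParams, rng: np.random.Generator,
    well_radius_mm: float = WELL_RADIUS_MM,
) -> LarvaState:
    r_max = max(well_radius_mm - params.body_axes[0], 0.05 * well_radius_mm)
    r = r_max * math.sqrt(rng.random())
    ang = rng.uniform(0.0, 2.0 * math.pi)
    return LarvaState(
        region=region,
        x=r * math.cos(ang),
        y=r * math.sin(ang),
        heading=rng.uniform(-math.pi, math.pi),
    )


def render_frame(
    larvae,
    layout: PlateLayout,
    spec: StimulusSpec,
    render: RenderSpec,
    t: float,
    direction: Direction,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one RGB frame: background, moving lines, larvae, optional noise.

    ``larvae`` is an iterable of ``(LarvaState, LarvaParams)`` pairs.  ``t``
    is seconds since the stimulus clock started; lines are drawn only when
    ``direction`` is "down" or "up".
    """
    h, w = layout.canvas_shape
    ppm = render.pixels_per_mm
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)

    if direction in _DIRVEC:
        off = stimulus_offset(spec, t, direction)
        y_mm = (np.arange(h) + 0.5) / ppm
        line_rows = ((y_mm - off) % spec.pitch) < spec.line_thickness
        img[line_rows] = np.asarray(render.line_rgb, dtype=np.uint8)

    for state, params in larvae:
        cx, cy = state.region.center
        px = cx + state.x * ppm
        py = cy + state.y * ppm
        a_px = params.body_axes[0] * ppm
        b_px = params.body_axes[1] * ppm
        if not (a_px <= px <= w - a_px and a_px <= py <= h - a_px):
            raise RenderError(
                f"larva at pixel ({px:.1f}, {py:.1f}) does not fit the "
                f"{w}x{h} image"
            )
        # skimage rotates counter-clockwise in (row, col); our heading is the
        # angle from +x toward +y, i.e. clockwise on screen.
        rr, cc = _draw_ellipse(py, px, b_px, a_px, shape=(h, w),
                               rotation=-state.heading)
        img[rr, cc] = np.asarray(params.body_intensity, dtype=np.uint8)

    if render.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        noisy = img.astype(np.float64) + rng.normal(0.0, render.noise_sd, img.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return img


def measure_line_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    pitch_px: float,
    channel: int = 1,
) -> int:
    """Vertical pattern displacement (pixels, downward) between two frames.

    Row-mean intensity profiles of one channel are cross-correlated over
    circular shifts within one pattern pitch; the argmax is the measured
    displacement.  The green channel carries the strongest line contrast in
    rendered frames.
    """
    pa = frame_a[..., channel].astype(float).mean(axis=1)
    pb = frame_b[..., channel].astype(float).mean(axis=1)
    pa -= pa.mean()
    pb -= pb.mean()
    shifts = np.arange(int(round(pitch_px)))
    scores = [float(np.dot(pb, np.roll(pa, s))) for s in shifts]
    return int(np.argmax(scores))


ParamsLike = (
    LarvaParams
    | Mapping[tuple[int, int], LarvaParams]
    | Mapping[tuple[int, int, int], LarvaParams]
    | Callable[[WellRegion], LarvaParams]
)


def _params_for(region: WellRegion, params: ParamsLike) -> LarvaParams:
    if isinstance(params, LarvaParams):
        return params
    if callable(params):
        return params(region)
    key3 = (region.plate, region.row, region.col)
    if key3 in params:
        return params[key3]
    key2 = (region.plate, region.row)
    if key2 in params:
        return params[key2]
    raise KeyError(f"no LarvaParams for well {key3}")


@dataclass
class SimulatedExperiment:
    """A fully simulated plate recording: trajectories plus lazy rendering.

    Trajectories are simulated once (deterministically from the seed, with
    one rng substream per larva derived from (seed, plate, row, col), so the
    result is independent of iteration order); frames are rasterized on
    demand to keep memory flat for long series.
    """

    layout: PlateLayout
    schedule: PeriodSchedule
    stimulus: StimulusSpec
    render: RenderSpec
    seed: int
    wells: list[WellRegion]
    params: list[LarvaParams]
    x: np.ndarray  # (n_larvae, n_frames) mm relative to well center
    y: np.ndarray
    heading: np.ndarray
    moved: np.ndarray  # bool (n_larvae, n_frames); frame 0 is False

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    def states_at(self, frame: int) -> list[tuple[LarvaState, LarvaParams]]:
        return [
            (
                LarvaState(
                    region=wellr,
                    x=float(self.x[i, frame]),
                    y=float(self.y[i, frame]),
                    heading=float(self.heading[i, frame]),
                ),
                self.params[i],
            )
            for i, wellr in enumerate(self.wells)
        ]

    def frame(self, i: int) -> np.ndarray:
        t = self.schedule.time_of_frame(i)
        _, direction = self.schedule.period_of_frame(i)
        rng = None
        if self.render.noise_sd > 0:
            rng = np.random.default_rng([self.seed, 999983, i])
        return render_frame(
            self.states_at(i), self.layout, self.stimulus, self.render,
            max(t, 0.0), direction, rng=rng,
        )

    def iter_frames(self) -> Iterator[np.ndarray]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def truth_table(self) -> pd.DataFrame:
        """Ground truth, one row per (larva, frame): position, moved flag,
        and the generating parameters."""
        n, f = self.x.shape
        frames = np.tile(np.arange(f), n)
        return pd.DataFrame(
            {
                "plate": np.repeat([w.plate for w in self.wells], f),
                "row": np.repeat([w.row for w in self.wells], f),
                "col": np.repeat([w.col for w in self.wells], f),
                "frame": frames,
                "x_mm": self.x.ravel(),
                "y_mm": self.y.ravel(),
                "heading": self.heading.ravel(),
                "moved": self.moved.ravel().astype(int),
                "p_move": np.repeat([p.p_move for p in self.params], f),
                "gain": np.repeat([p.optomotor_gain for p in self.params], f),
            }
        )

    def write(self, outdir: str | Path, *, frames: bool = True) -> dict[str, Path]:
        """Write numbered PNG frames, ground_truth.csv, and the generating
        config; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if frames:
            for i, img in enumerate(self.iter_frames()):
                p = outdir / f"frame_{i + 1:06d}.png"
                try:
                    iio.imwrite(p, img)
                except OSError as exc:
                    raise OSError(f"failed writing frame to {p}: {exc}") from exc
            paths["frames"] = outdir
        truth_path = outdir / "ground_truth.csv"
        self.truth_table().to_csv(truth_path, index=False)
        paths["ground_truth"] = truth_path
        import yaml

        cfg = {
            "seed": self.seed,
            "layout": self.layout.to_dict(),
            "schedule": self.schedule.to_dict(),
            "stimulus": self.stimulus.to_dict(),
            "render": self.render.to_dict(),
        }
        cfg_path = outdir / "simulation_config.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        paths["config"] = cfg_path
        return paths


def simulate_experiment(
    layout: PlateLayout,
    schedule: PeriodSchedule,
    params: ParamsLike,
    seed: int,
    *,
    stimulus: StimulusSpec | None = None,
    render: RenderSpec | None = None,
) -> SimulatedExperiment:
    """Simulate every larva over the full schedule.

    ``params`` may be a single LarvaParams for all wells, a mapping keyed by
    (plate, row) or (plate, row, col) — mirroring row-based treatment-group
    designs — or a callable of the WellRegion.
    """
    stimulus = stimulus or StimulusSpec()
    render = render or RenderSpec()
    wells = layout.wells()
    n_frames = schedule.n_frames
    n = len(wells)
    xs = np.empty((n, n_frames))
    ys = np.empty((n, n_frames))
    hd = np.empty((n, n_frames))
    mv = np.zeros((n, n_frames), dtype=bool)
    plist: list[LarvaParams] = []
    directions = [schedule.period_of_frame(f)[1] for f in range(n_frames)]
    for i, wellr in enumerate(wells):
        p = _params_for(wellr, params)
        plist.append(p)
        rng = np.random.default_rng([seed, 1, wellr.plate, wellr.row, wellr.col])
        state = _initial_state(wellr, p, rng)
        xs[i, 0], ys[i, 0], hd[i, 0] = state.x, state.y, state.heading
        for f in range(1, n_frames):
            state, moved = step_larva(state, p, directions[f], rng)
            xs[i, f], ys[i, f], hd[i, f] = state.x, state.y, state.heading
            mv[i, f] = moved
    log.info("simulated %d larvae over %d frames (seed=%s)", n, n_frames, seed)
    return SimulatedExperiment(
        layout=layout,
        schedule=schedule,
        stimulus=stimulus,
        render=render,
        seed=seed,
        wells=wells,
        params=plist,
        x=xs,
        y=ys,
        heading=hd,
        moved=mv,
    )


def simulate_scores(
    n_larvae: int,
    params: LarvaParams,
    schedule: PeriodSchedule,
    seed: int,
) -> pd.DataFrame:
    """Render-free behavioral scores: simulate trajectories only and score
    them with perfect detection (moved flag and upper/lower half straight
    from the agent state).

    Useful for Monte-Carlo studies of the statistics where rasterizing and
    re-detecting thousands of plate series would add nothing: columns are
    larva, activity_pct, eo, eo_valid.
    """
    from .scoring import eo_statistic

    region = WellRegion(plate=0, row=0, col=0, bbox=(0, 0, 64, 64))
    n_frames = schedule.n_frames
    up_p, down_p = schedule.up_periods, schedule.down_periods
    rows = []
    for i in range(n_larvae):
        rng = np.random.default_rng([seed, 2, i])
        state = _initial_state(region, params, rng)
        moved_ct = 0
        scored_ct = 0
        up_ct: dict[int, int] = {}
        def_ct: dict[int, int] = {}
        for f in range(1, n_frames):
            pid, direction = schedule.period_of_frame(f)
            state, moved = step_larva(state, params, direction, rng)
            if pid == 0:
                continue
            scored_ct += 1
            if moved:
                moved_ct += 1
                def_ct[pid] = def_ct.get(pid, 0) + 1
                if state.y < 0:
                    up_ct[pid] = up_ct.get(pid, 0) + 1
        activity = 100.0 * moved_ct / scored_ct if scored_ct else np.nan
        up_pct = {
            pid: 100.0 * up_ct.get(pid, 0) / cnt for pid, cnt in def_ct.items()
        }
        eo = eo_statistic(up_pct, even=up_p, odd=down_p)
        rows.append(
            {
                "larva": i,
                "activity_pct": activity,
                "eo": eo,
                "eo_valid": bool(np.isfinite(eo) and activity >= 5.0),
            }
        )
    return pd.DataFrame(rows)
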