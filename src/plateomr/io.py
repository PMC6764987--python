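"""Configuration, frame loading, and the end-to-end pipeline run.

``run_all`` ties simulate -> detect -> score -> stats into one reproducible
run: given a config and a seed it emits the detection results table, larva
scores, group summaries, a stats report, a per-period summary figure, and a
manifest with the resolved config — all as plain CSV/JSON/YAML so a run can
be scripted, diffed, and rerun bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from . import __version__
from .detect import DetectionConfig, run_detection
from .geometry import PlateLayout, standard_layout
from .schedule import PeriodSchedule, StimulusSpec
from .scoring import assign_groups, per_period_scores, score_larvae, summarize_group
from .simulate import LarvaParams, PRESETS, RenderSpec, simulate_experiment
from .stats import compare_groups

log = logging.getLogger(__name__)

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


class FrameFormatError(ValueError):
    """A frame file is missing, corrupt, or inconsistent with the series."""


class FrameSeries:
    """Lazy, validated access to an on-disk image series.

    Frames are ordered lexicographically by filename (acquisition software
    numbers frames, so lexicographic order is time order).  All image
    headers are checked up front so dimension mismatches and corrupt files
    fail early with the offending file named.  Images load as 8-bit RGB;
    higher bit depths are rescaled with a warning.
    """

    def __init__(self, paths: Sequence[Path], frame_interval: float = 6.0):
        if not paths:
            raise FrameFormatError("empty input: no frames to load")
        self.paths = [Path(p) for p in paths]
        self.frame_interval = frame_interval
        self.shape: tuple[int, int] | None = None
        for p in self.paths:
            try:
                with Image.open(p) as im:
                    size = (im.height, im.width)
            except (UnidentifiedImageError, OSError) as exc:
                raise FrameFormatError(f"cannot read frame {p}: {exc}") from exc
            if self.shape is None:
                self.shape = size
            elif size != self.shape:
                raise FrameFormatError(
                    f"frame {p} is {size[1]}x{size[0]} but the series is "
                    f"{self.shape[1]}x{self.shape[0]}"
                )
        self._warned_depth = False

    def __len__(self) -> int:
        return len(self.paths)

    def __getitem__(self, i: int) -> np.ndarray:
        p = self.paths[i]
        try:
            arr = iio.imread(p)
        except (OSError, ValueError) as exc:
            raise FrameFormatError(f"cannot read frame {p}: {exc}") from exc
        if arr.dtype != np.uint8:
            if not self._warned_depth:
                warnings.warn(
                    f"{p.name}: rescaling {arr.dtype} frames to 8-bit", stacklevel=2
                )
                self._warned_depth = True
            info = np.iinfo(arr.dtype) if arr.dtype.kind in "iu" else None
            top = info.max if info else max(float(arr.max()), 1.0)
            arr = (arr.astype(np.float64) * (255.0 / top)).round().astype(np.uint8)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        elif arr.shape[2] > 3:
            arr = arr[..., :3]
        return arr

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def load_frames(directory: str | Path, frame_interval: float = 6.0) -> FrameSeries:
    """Load a directory of PNG/TIFF/JPEG frames as a validated series."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FrameFormatError(f"not a directory: {directory}")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not paths:
        raise FrameFormatError(f"empty input: no image files in {directory}")
    return FrameSeries(paths, frame_interval=frame_interval)


def _default_groups() -> dict[str, list[tuple[int, int]]]:
    # standard design: four rows of controls, two rows per treatment group
    return {
        "untreated": [(0, r) for r in range(4)],
        "blind": [(0, 4), (0, 5)],
        "immotile": [(0, 6), (0, 7)],
    }


@dataclass
class RunConfig:
    """Everything one reproducible run needs; round-trips through YAML."""

    seed: int = 0
    layout: PlateLayout = field(default_factory=lambda: standard_layout(1, 8, 12))
    schedule: PeriodSchedule = field(default_factory=PeriodSchedule)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    render: RenderSpec = field(default_factory=RenderSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    activity_floor: float = 5.0
    groups: dict[str, list[tuple[int, int]]] = field(default_factory=_default_groups)
    params: dict[str, LarvaParams] = field(
        default_factory=lambda: {k: PRESETS[k] for k in ("untreated", "blind", "immotile")}
    )
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("blind", "untreated"), ("immotile", "untreated")]
    )
    input_dir: str | None = None

    def group_map(self) -> dict[tuple[int, int], str]:
        out: dict[tuple[int, int], str] = {}
        for label, rows in self.groups.items():
            for plate, row in rows:
                out[(int(plate), int(row))] = label
        return out

    def params_map(self) -> dict[tuple[int, int], LarvaParams]:
        gm = self.group_map()
        missing = [lbl for lbl in set(gm.values()) if lbl not in self.params]
        if missing:
            raise ValueError(f"groups without LarvaParams: {missing}")
        return {key: self.params[lbl] for key, lbl in gm.items()}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "layout": self.layout.to_dict(),
            "schedule": self.schedule.to_dict(),
            "stimulus": self.stimulus.to_dict(),
            "render": self.render.to_dict(),
            "detection": {
                "diff_threshold": self.detection.diff_threshold,
                "move_area_min": self.detection.move_area_min,
                "channel": self.detection.channel,
                "mode": self.detection.mode,
            },
            "activity_floor": self.activity_floor,
            "groups": {k: [list(t) for t in v] for k, v in self.groups.items()},
            "params": {k: v.to_dict() for k, v in self.params.items()},
            "contrasts": [list(t) for t in self.contrasts],
            "input_dir": self.input_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "layout" in kw:
            lay = kw["layout"]
            kw["layout"] = (
                standard_layout(**{k: v for k, v in lay.items() if k != "kind"})
                if lay.get("kind") == "standard"
                else PlateLayout.from_dict(lay)
            )
        if "schedule" in kw:
            kw["schedule"] = PeriodSchedule.from_dict(kw["schedule"])
        if "stimulus" in kw:
            kw["stimulus"] = StimulusSpec.from_dict(kw["stimulus"])
        if "render" in kw:
            kw["render"] = RenderSpec.from_dict(kw["render"])
        if "detection" in kw:
            kw["detection"] = DetectionConfig(**kw["detection"])
        if "groups" in kw:
            kw["groups"] = {
                k: [tuple(int(x) for x in t) for t in v] for k, v in kw["groups"].items()
            }
        if "params" in kw:
            kw["params"] = {k: LarvaParams.from_dict(v) for k, v in kw["params"].items()}
        if "contrasts" in kw:
            kw["contrasts"] = [tuple(t) for t in kw["contrasts"]]
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def plot_period_means(
    period_scores: pd.DataFrame,
    group_map: Mapping[tuple[int, int], str],
    path: str | Path,
) -> None:
    """Two-panel figure of per-period group means: activity and %up."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    df = period_scores.copy()
    df["group"] = [
        group_map.get((p, r)) for p, r in zip(df["plate"], df["row"])
    ]
    df = df[df["group"].notna()]
    fig = Figure(figsize=(8, 6))
    FigureCanvasAgg(fig)
    ax1, ax2 = fig.subplots(2, 1, sharex=True)
    for label, sub in df.groupby("group"):
        means = sub.groupby("period")[["activity_pct", "up_pct"]].mean()
        ax1.plot(means.index, means["activity_pct"], marker="o", label=label)
        ax2.plot(means.index, means["up_pct"], marker="o", label=label)
    ax1.set_ylabel("activity (lmpi, %)")
    ax2.set_ylabel("larvae up in well (%)")
    ax2.set_xlabel("10-minute period")
    ax1.legend(fontsize=8)
    ax1.set_title("Per-period group means")
    fig.tight_layout()
    fig.savefig(path, dpi=110)


@dataclass
class RunResult:
    """Paths and headline tables of one pipeline run."""

    out_dir: Path
    results: pd.DataFrame
    scores: pd.DataFrame
    group_summary: pd.DataFrame
    stats_report: pd.DataFrame
    paths: dict[str, Path]


def run_all(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute the full chain and write all artifacts under ``out_dir``.

    With ``config.input_dir`` set, frames are read from disk; otherwise a
    synthetic experiment is simulated from the group presets.  Identical
    (config, seed) give byte-identical CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    t0 = time.perf_counter()

    stage = "simulate/load"
    try:
        if config.input_dir:
            frames = load_frames(config.input_dir, config.schedule.frame_interval)
            n_frames = len(frames)
        else:
            exp = simulate_experiment(
                config.layout,
                config.schedule,
                config.params_map(),
                config.seed,
                stimulus=config.stimulus,
                render=config.render,
            )
            truth_path = out / "ground_truth.csv"
            exp.truth_table().to_csv(truth_path, index=False)
            paths["ground_truth"] = truth_path
            frames = exp.iter_frames()
            n_frames = exp.n_frames

        stage = "detect"
        results = run_detection(
            frames, config.layout, config.schedule, config.detection,
            stimulus=config.stimulus,
        )
        paths["results"] = out / "results.csv"
        results.to_csv(paths["results"], index=False)

        stage = "score"
        scores = score_larvae(results, config.schedule, config.activity_floor)
        gmap = config.group_map()
        scores = assign_groups(scores, gmap)
        paths["larva_scores"] = out / "larva_scores.csv"
        scores.to_csv(paths["larva_scores"], index=False)
        summary = summarize_group(scores)
        paths["group_summary"] = out / "group_summary.csv"
        summary.to_csv(paths["group_summary"], index=False)

        stage = "stats"
        report = compare_groups(scores, config.contrasts)
        paths["stats_report"] = out / "stats_report.csv"
        report.to_csv(paths["stats_report"], index=False)

        stage = "report"
        paths["figure"] = out / "figure.png"
        plot_period_means(per_period_scores(results), gmap, paths["figure"])
        paths["config"] = out / "config.yaml"
        config.to_yaml(paths["config"])
        cfg_text = paths["config"].read_text()
        manifest = {
            "tool": "plateomr",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "n_frames": int(n_frames),
            "n_wells": config.layout.n_wells,
            "n_result_rows": int(len(results)),
            "elapsed_s": round(time.perf_counter() - t0, 2),
        }
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    log.info("run_all finished in %.1fs -> %s", time.perf_counter() - t0, out)
    return RunResult(
        out_dir=out,
        results=results,
        scores=scores,
        group_summary=summary,
        stats_report=report,
        paths=paths,
    )
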