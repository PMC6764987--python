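"""Shared test utilities: synthetic difference images, parameter sweeps, and
Monte-Carlo calibration helpers used by both the module tests and the
acceptance checks."""

from __future__ import annotations

import numpy as np

from plateomr import (
    DetectionConfig,
    RenderSpec,
    StimulusSpec,
    WellRegion,
    bin_scores,
    chi2_homogeneity,
    measure_line_shift,
    measure_well,
    render_frame,
    standard_layout,
)

SINGLE_WELL = WellRegion(plate=0, row=0, col=0, bbox=(0, 0, 40, 40))


def blob_diff_image(n_pixels: int, intensity: int = 200, size: int = 40) -> np.ndarray:
    """A single-well difference image containing one compact blob of exactly
    ``n_pixels`` pixels at the given intensity."""
    img = np.zeros((size, size), dtype=np.uint8)
    side = int(np.ceil(np.sqrt(n_pixels)))
    block = np.zeros(side * side, dtype=bool)
    block[:n_pixels] = True
    img[10 : 10 + side, 10 : 10 + side][block.reshape(side, side)] = intensity
    return img


def min_move_area() -> int:
    """Sweep blob areas 1..50; smallest area labelled as movement."""
    cfg = DetectionConfig()
    for k in range(1, 51):
        if measure_well(blob_diff_image(k), SINGLE_WELL, cfg).move == 1:
            return k
    raise AssertionError("no blob up to 50 px scored as movement")


def min_foreground_intensity() -> int:
    """Sweep uniform blob intensities 0..255; smallest counted as foreground."""
    cfg = DetectionConfig()
    for v in range(0, 256):
        if measure_well(blob_diff_image(100, intensity=v), SINGLE_WELL, cfg).area > 0:
            return v
    raise AssertionError("no intensity up to 255 counted as foreground")


def stimulus_displacement_mm(dt: float = 8.0, pixels_per_mm: float = 10.0) -> float:
    """Render larva-free frames ``dt`` seconds apart and measure the line
    pattern displacement by row-wise cross-correlation, in mm."""
    layout = standard_layout(1, 2, 12, pixels_per_mm=pixels_per_mm)
    spec = StimulusSpec()
    rend = RenderSpec(pixels_per_mm=pixels_per_mm)
    f0 = render_frame([], layout, spec, rend, 0.0, "down")
    f1 = render_frame([], layout, spec, rend, dt, "down")
    shift_px = measure_line_shift(f0, f1, pitch_px=spec.pitch * pixels_per_mm)
    return shift_px / pixels_per_mm


def homogeneity_type1_rate(
    seed: int, replicates: int = 200, n_a: int = 48, n_b: int = 24,
    n_intervals: int = 1199, alpha: float = 0.05,
) -> float:
    """Rejection percentage of the quartile-binned homogeneity test when both
    groups share identical behavioral parameters (p_move = 0.5)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(replicates):
        a = 100.0 * rng.binomial(n_intervals, 0.5, size=n_a) / n_intervals
        b = 100.0 * rng.binomial(n_intervals, 0.5, size=n_b) / n_intervals
        cmp = chi2_homogeneity(bin_scores(a), bin_scores(b))
        rejections += cmp.p < alpha
    return 100.0 * rejections / replicates


def brute_force_chi2(table: np.ndarray) -> tuple[float, int]:
    """Independent chi-squared oracle: explicit sum of (O-E)^2/E with
    expected counts from the margins, via plain Python loops."""
    table = np.asarray(table, dtype=float)
    r, k = table.shape
    total = table.sum()
    stat = 0.0
    for i in range(r):
        for j in range(k):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat, (r - 1) * (k - 1)
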