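"""Plate, row, and well geometry for multi-well behavioral imaging.

The analysis works on raster images of up to four 96-well plates.  The user
(or a config file) outlines each physical row of wells with a pixel-space
rectangle; a row outline is then partitioned into equal-width well regions,
one per well, which are the units of all downstream measurement.

Coordinate convention: image origin at the top-left, x rightward (columns),
y downward (rows).  All rectangles are half-open ``[x0, x1) x [y0, y1)``.
"Up" inside a well therefore means *smaller* y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

#: Inner diameter of a shallow-well ("ProxiPlate"-style) 96-well plate well, mm.
WELL_DIAMETER_MM = 7.15
#: Depth of the shallow wells, mm.  Shallow wells give larvae an effectively
#: two-dimensional swimming arena, which is what the simulator assumes.
WELL_DEPTH_MM = 3.25


class GeometryError(ValueError):
    """Invalid plate/row/well geometry."""


Rect = tuple[int, int, int, int]


def _validate_rect(bbox: Sequence[float], what: str = "rectangle") -> Rect:
    if len(bbox) != 4:
        raise GeometryError(f"{what} must be (x0, y0, x1, y1), got {bbox!r}")
    x0, y0, x1, y1 = (int(v) for v in bbox)
    if x1 <= x0 or y1 <= y0:
        raise GeometryError(f"{what} has non-positive width/height: {bbox!r}")
    return (x0, y0, x1, y1)


@dataclass(frozen=True)
class WellRegion:
    """One well's analysis region: a pixel rectangle plus its plate/row/column
    address and an optional circular mask refinement.

    The default mask is the full rectangle, mirroring region-based measurement
    of a thresholded selection; circular masking (restricting to the physical
    well of diameter 7.15 mm when the pixel scale is known) is opt-in.
    """

    plate: int
    row: int
    col: int
    bbox: Rect
    mask_shape: str = "rectangle"
    well_diameter_px: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bbox", _validate_rect(self.bbox, "well bbox"))
        if self.mask_shape not in ("rectangle", "circle"):
            raise GeometryError(f"unknown mask_shape {self.mask_shape!r}")
        if self.mask_shape == "circle" and not self.well_diameter_px:
            raise GeometryError("circular mask requires well_diameter_px")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    @property
    def width(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def height(self) -> int:
        return self.bbox[3] - self.bbox[1]

    @property
    def area(self) -> int:
        return self.width * self.height

    def pixel_mask(self) -> np.ndarray:
        """Boolean mask of analysed pixels, shaped (height, width)."""
        if self.mask_shape == "rectangle":
            return np.ones((self.height, self.width), dtype=bool)
        cy = (self.height - 1) / 2.0
        cx = (self.width - 1) / 2.0
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        r = self.well_diameter_px / 2.0
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bbox
        return x0 <= x < x1 and y0 <= y < y1


def well_center(region: WellRegion) -> tuple[float, float]:
    """Geometric center ``((x0+x1)/2, (y0+y1)/2)`` of a well region.

    Used by the up/down rule: a larva is "up" when its centroid's y is
    smaller than the well center's y.
    """
    return region.center


def partition_row(
    outline: Sequence[float],
    n_wells: int,
    *,
    plate: int = 0,
    row: int = 0,
    mask_shape: str = "rectangle",
    well_diameter_px: float | None = None,
) -> list[WellRegion]:
    """Partition one row outline into ``n_wells`` equal-width well regions.

    Widths are equal up to the integer remainder of the division; any extra
    pixels go to the leftmost regions, so the regions tile the outline exactly
    and are ordered left to right by column.
    """
    if n_wells < 1:
        raise GeometryError(f"n_wells must be >= 1, got {n_wells}")
    x0, y0, x1, y1 = _validate_rect(outline, "row outline")
    width = x1 - x0
    if width < n_wells:
        raise GeometryError(
            f"row outline width {width} px cannot hold {n_wells} wells"
        )
    base, extra = divmod(width, n_wells)
    regions = []
    left = x0
    for col in range(n_wells):
        w = base + (1 if col < extra else 0)
        regions.append(
            WellRegion(
                plate=plate,
                row=row,
                col=col,
                bbox=(left, y0, left + w, y1),
                mask_shape=mask_shape,
                well_diameter_px=well_diameter_px,
            )
        )
        left += w
    return regions


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of all plates in the field of view.

    ``row_outlines`` holds one pixel rectangle per physical row of wells,
    ordered plate-major (all rows of plate 0, then plate 1, ...).
    ``pixel_scale_um`` is the physical size of one pixel in micrometres
    (48.3 on the original rig); it is required only for circular masking.
    """

    n_plates: int
    rows_per_plate: int
    wells_per_row: int
    row_outlines: tuple[Rect, ...]
    pixel_scale_um: float | None = None
    mask_shape: str = "rectangle"

    def __post_init__(self) -> None:
        if min(self.n_plates, self.rows_per_plate, self.wells_per_row) < 1:
            raise GeometryError("plate/row/well counts must be >= 1")
        outlines = tuple(_validate_rect(r, "row outline") for r in self.row_outlines)
        object.__setattr__(self, "row_outlines", outlines)
        expected = self.n_plates * self.rows_per_plate
        if len(outlines) != expected:
            raise GeometryError(
                f"expected {expected} row outlines "
                f"({self.n_plates} plates x {self.rows_per_plate} rows), "
                f"got {len(outlines)}"
            )
        if self.mask_shape == "circle" and self.pixel_scale_um is None:
            raise GeometryError("circular masks require pixel_scale_um")

    @property
    def n_wells(self) -> int:
        return self.n_plates * self.rows_per_plate * self.wells_per_row

    @property
    def well_diameter_px(self) -> float | None:
        if self.pixel_scale_um is None:
            return None
        return WELL_DIAMETER_MM * 1000.0 / self.pixel_scale_um

    @property
    def canvas_shape(self) -> tuple[int, int]:
        """(height, width) of the smallest image symmetric around the outlines."""
        x0 = min(r[0] for r in self.row_outlines)
        y0 = min(r[1] for r in self.row_outlines)
        x1 = max(r[2] for r in self.row_outlines)
        y1 = max(r[3] for r in self.row_outlines)
        return (y1 + y0, x1 + x0)

    def outline_of(self, plate: int, row: int) -> Rect:
        return self.row_outlines[plate * self.rows_per_plate + row]

    def wells(self) -> list[WellRegion]:
        """All well regions, ordered (plate, row, col)."""
        out: list[WellRegion] = []
        for plate in range(self.n_plates):
            for row in range(self.rows_per_plate):
                out.extend(
                    partition_row(
                        self.outline_of(plate, row),
                        self.wells_per_row,
                        plate=plate,
                        row=row,
                        mask_shape=self.mask_shape,
                        well_diameter_px=self.well_diameter_px,
                    )
                )
        return out

    def well_at(self, x: float, y: float) -> WellRegion | None:
        """Map a pixel to the unique well region containing it (None outside)."""
        for region in self.wells():
            if region.contains(x, y):
                return region
        return None

    def to_dict(self) -> dict:
        d = {
            "n_plates": self.n_plates,
            "rows_per_plate": self.rows_per_plate,
            "wells_per_row": self.wells_per_row,
            "row_outlines": [list(r) for r in self.row_outlines],
            "mask_shape": self.mask_shape,
        }
        if self.pixel_scale_um is not None:
            d["pixel_scale_um"] = self.pixel_scale_um
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        return cls(
            n_plates=int(d["n_plates"]),
            rows_per_plate=int(d["rows_per_plate"]),
            wells_per_row=int(d["wells_per_row"]),
            row_outlines=tuple(tuple(r) for r in d["row_outlines"]),
            pixel_scale_um=d.get("pixel_scale_um"),
            mask_shape=d.get("mask_shape", "rectangle"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "layout" in d:  # allow a full run config file
            d = d["layout"]
        return cls.from_dict(d)


def standard_layout(
    n_plates: int = 4,
    rows_per_plate: int = 8,
    wells_per_row: int = 12,
    *,
    pixels_per_mm: float = 4.0,
    well_pitch_mm: float = 9.0,
    margin_mm: float = 4.0,
    plate_gap_mm: float = 6.0,
    mask_shape: str = "rectangle",
) -> PlateLayout:
    """Build the standard stacked-plate layout used by the simulator.

    Plates are stacked vertically; each row outline is a ``wells_per_row x 1``
    strip of 9 mm well pitch (the standard 96-well pitch).  The default
    4 x 8 x 12 configuration gives 384 wells.
    """
    ppm = pixels_per_mm
    row_w = int(round(wells_per_row * well_pitch_mm * ppm))
    row_h = int(round(well_pitch_mm * ppm))
    x0 = int(round(margin_mm * ppm))
    outlines = []
    for plate in range(n_plates):
        plate_y0 = margin_mm + plate * (rows_per_plate * well_pitch_mm + plate_gap_mm)
        for row in range(rows_per_plate):
            y0 = int(round((plate_y0 + row * well_pitch_mm) * ppm))
            outlines.append((x0, y0, x0 + row_w, y0 + row_h))
    return PlateLayout(
        n_plates=n_plates,
        rows_per_plate=rows_per_plate,
        wells_per_row=wells_per_row,
        row_outlines=tuple(outlines),
        pixel_scale_um=1000.0 / ppm,
        mask_shape=mask_shape,
    )
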