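"""Size and shape measurements from the two segmentation masks.

The top mask yields major/minor axis lengths, area and perimeter in
pixels; the side mask yields the seed height as twice the longest
perpendicular segment from the equatorial midline to the top edge of the
reflected profile (the prism shows only the upper half of the seed).
Pixel measures become millimetres through the size calibration: top-view
lengths scale with the top slope, areas with its square, and the height
with the depth-interpolated side slope at the seed's midline column.

The seed is modelled as a tri-axial ellipsoid with semi-axes
(major/2, minor/2, height/2) to derive volume and surface area, and three
dimensionless indices describe shape, each equal to 1 for a perfect
circle or sphere:

    roundness   = 4 A / (pi * major^2)          (area vs circumscribed circle)
    circularity = 4 pi A / P^2                  (area vs perimeter)
    sphericity  = pi^(1/3) (6 V)^(2/3) / S      (volume vs surface area)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .sizecal import SizeCalibration, side_scale_at

#: exponent of the Thomsen approximation for tri-axial ellipsoid surface
#: area (worst-case relative error about 1.06%)
THOMSEN_P = 1.6075


@dataclass
class ShapeRecord:
    """Per-seed size and shape measurements, in pixels and millimetres."""

    major_axis_px: float
    minor_axis_px: float
    height_px: float
    area_px: float
    perimeter_px: float
    major_axis_mm: float
    minor_axis_mm: float
    height_mm: float
    area_mm2: float
    perimeter_mm: float
    volume_mm3: float
    surface_area_mm2: float
    roundness: float
    circularity: float
    sphericity: float


def top_props(top_mask: np.ndarray) -> dict:
    """Pixel-space properties of the top-view mask.

    Area is the pixel count; major/minor axis lengths come from the
    ellipse with matching second central moments; the perimeter uses the
    Crofton estimator (intersections with a family of test lines), which
    is within a few tenths of a percent on smooth rasterised shapes where
    boundary-step counting over-reads by about 5% and would bias the
    circularity index low.
    """
    mask = np.asarray(top_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    perim = float(props.perimeter_crofton) if props.area > 1 else 4.0
    return {
        "area": float(props.area),
        "major": float(props.axis_major_length),
        "minor": float(props.axis_minor_length),
        "perimeter": perim,
    }


def height_px(side_mask: np.ndarray, midline_row: int) -> float:
    """Seed height in pixels from the half-profile above the midline.

    Twice the maximum over columns of (midline_row - topmost mask row);
    columns without mask pixels are ignored.
    """
    mask = np.asarray(side_mask, dtype=bool)
    cols = np.nonzero(mask.any(axis=0))[0]
    if len(cols) == 0:
        raise ValueError("empty side mask")
    tops = np.argmax(mask[:, cols], axis=0)  # first True row per column
    half = midline_row - tops
    if half.max() <= 0:
        raise ValueError("side mask lies entirely below the midline")
    return 2.0 * float(half.max())


def to_mm(props_px: dict, calib: SizeCalibration, midline_x_px: float) -> dict:
    """Convert pixel properties to physical units.

    Top-view lengths multiply by the top slope and areas by its square;
    the height multiplies by the side scale interpolated at the seed's
    midline column.
    """
    s = calib.top.slope_mm_per_px
    out = {
        "major": props_px["major"] * s,
        "minor": props_px["minor"] * s,
        "area": props_px["area"] * s * s,
        "perimeter": props_px["perimeter"] * s,
    }
    if "height" in props_px:
        out["height"] = props_px["height"] * side_scale_at(calib, midline_x_px)
    return out


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of a tri-axial ellipsoid with semi-axes a, b, c."""
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface(a: float, b: float, c: float) -> float:
    """Thomsen approximation to the tri-axial ellipsoid surface area.

    S ~ 4 pi [((ab)^p + (ac)^p + (bc)^p) / 3]^(1/p) with p = 1.6075;
    exact for a sphere, within about 1.1% in general.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    p = THOMSEN_P
    ab, ac, bc = (a * b) ** p, (a * c) ** p, (b * c) ** p
    return 4.0 * np.pi * ((ab + ac + bc) / 3.0) ** (1.0 / p)


def _clip_index(value: float, name: str) -> float:
    if value > 1.0 + 1e-9 or value < -1e-9:
        raise ValueError(f"{name} {value:.4f} outside [0, 1]")
    return float(min(max(value, 0.0), 1.0))


def roundness(area: float, major_axis: float) -> float:
    """4 A / (pi major^2): area relative to the circumscribed circle."""
    if major_axis <= 0:
        raise ValueError("major axis must be positive")
    return _clip_index(4.0 * area / (np.pi * major_axis**2), "roundness")


def circularity(area: float, perimeter: float) -> float:
    """4 pi A / P^2: the isoperimetric quotient."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return _clip_index(4.0 * np.pi * area / perimeter**2, "circularity")


def sphericity(volume: float, surface_area: float) -> float:
    """pi^(1/3) (6 V)^(2/3) / S: surface of the equal-volume sphere over S."""
    if surface_area <= 0:
        raise ValueError("surface area must be positive")
    value = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area
    return _clip_index(value, "sphericity")


def measure_seed(
    top_mask: np.ndarray,
    side_mask: np.ndarray,
    midline_row: int,
    calib: SizeCalibration,
    midline_x_px: float,
) -> ShapeRecord:
    """Full morphometric record from the two masks of one seed."""
    px = top_props(top_mask)
    px["height"] = height_px(side_mask, midline_row)
    mm = to_mm(px, calib, midline_x_px)
    a, b, c = mm["major"] / 2, mm["minor"] / 2, mm["height"] / 2
    vol = ellipsoid_volume(a, b, c)
    surf = ellipsoid_surface(a, b, c)
    return ShapeRecord(
        major_axis_px=px["major"], minor_axis_px=px["minor"],
        height_px=px["height"], area_px=px["area"], perimeter_px=px["perimeter"],
        major_axis_mm=mm["major"], minor_axis_mm=mm["minor"],
        height_mm=mm["height"], area_mm2=mm["area"], perimeter_mm=mm["perimeter"],
        volume_mm3=vol, surface_area_mm2=surf,
        roundness=roundness(px["area"], px["major"]),
        circularity=circularity(px["area"], px["perimeter"]),
        sphericity=sphericity(vol, surf),
    )


def cylinder_diameter_px(top_mask: np.ndarray, min_columns: int = 10) -> float:
    """Median per-column width of a cylinder mask laid along the belt axis."""
    mask = np.asarray(top_mask, dtype=bool)
    widths = mask.sum(axis=0)
    widths = widths[widths > 0]
    if len(widths) < min_columns:
        raise ValueError("cylinder mask spans too few columns")
    return float(np.median(widths))
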