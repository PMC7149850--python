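"""Pixel-to-millimetre size calibration from ruler images.

A millimetre ruler is imaged in three poses: flat on the belt (top view),
against the prism (near side view) and at the far edge of the lane (far
side view).  For each pose, a Sobel gradient is summed across the tick
marks to produce a periodic signal whose positive peaks sit on the
white-to-dark tick edges; an ordinary least-squares fit of cumulative
nominal distance against peak pixel position gives the mm-per-pixel slope.
Side-view measurements are then scaled by linear interpolation between the
near and far slopes according to the object's column position, which acts
as a proxy for its distance from the prism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.signal import find_peaks


@dataclass(frozen=True)
class LinearScale:
    """One view's linear fit of physical distance against pixel position."""

    slope_mm_per_px: float
    intercept_mm: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope_mm_per_px <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class SizeCalibration:
    """Complete size calibration: top scale plus depth-interpolated side scale."""

    top: LinearScale
    near_side: LinearScale
    far_side: LinearScale
    near_endpoint_px: float
    far_endpoint_px: float

    def __post_init__(self) -> None:
        if self.near_endpoint_px == self.far_endpoint_px:
            raise ValueError("interpolation endpoints must be distinct")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SizeCalibration":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("top", "near_side", "far_side"):
            d[key] = LinearScale(**d[key])
        return cls(**d)


def tick_positions(ruler_image: np.ndarray, axis: str = "x") -> np.ndarray:
    """Detect sub-pixel tick-edge positions along the ruler axis.

    A Sobel derivative is taken along the axis, summed across the
    perpendicular direction, and the positive peaks of the inverted signal
    (white-to-dark transitions) are located and refined with a three-point
    parabolic fit.
    """
    img = np.asarray(ruler_image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if axis == "x":
        grad = ndimage.sobel(img, axis=1)
        signal = -grad.sum(axis=0)  # positive at white->dark edges
    elif axis == "y":
        grad = ndimage.sobel(img, axis=0)
        signal = -grad.sum(axis=1)
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if np.ptp(signal) <= 0:
        raise ValueError("no tick transitions found (uniform image)")
    peaks, _ = find_peaks(signal, height=0.5 * signal.max(),
                          distance=max(2, len(signal) // 1000))
    if len(peaks) < 2:
        raise ValueError(f"found {len(peaks)} tick transitions; need at least 2")
    refined = []
    for p in peaks:
        if 0 < p < len(signal) - 1:
            y0, y1, y2 = signal[p - 1: p + 2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            refined.append(p + float(np.clip(delta, -0.5, 0.5)))
        else:
            refined.append(float(p))
    return np.asarray(refined)


def fit_scale(positions: np.ndarray, tick_spacing_mm: float = 1.0) -> LinearScale:
    """OLS fit of cumulative nominal distance k * spacing against pixel position."""
    pos = np.sort(np.asarray(positions, dtype=float))
    if len(pos) < 3:
        raise ValueError("need at least 3 tick positions")
    if np.ptp(pos) == 0:
        raise ValueError("degenerate positions (all identical)")
    mm = tick_spacing_mm * np.arange(len(pos))
    slope, intercept = np.polyfit(pos, mm, 1)
    fitted = slope * pos + intercept
    ss_res = float(np.sum((mm - fitted) ** 2))
    ss_tot = float(np.sum((mm - mm.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return LinearScale(float(slope), float(intercept), r2)


def calibrate_view(ruler_image: np.ndarray, tick_spacing_mm: float = 1.0,
                   axis: str = "x") -> LinearScale:
    """Tick detection plus linear fit in one call."""
    return fit_scale(tick_positions(ruler_image, axis), tick_spacing_mm)


def side_scale_at(calib: SizeCalibration, x_px: float) -> float:
    """mm-per-pixel for side-view measurements of an object at column x_px.

    Linear interpolation of the slope between the near and far endpoints,
    clamped to the endpoint values outside the range so that masks near
    the crop edges never produce runaway scales.
    """
    lo, hi = calib.near_endpoint_px, calib.far_endpoint_px
    t = (x_px - lo) / (hi - lo)
    t = min(max(t, 0.0), 1.0)
    return (calib.near_side.slope_mm_per_px
            + t * (calib.far_side.slope_mm_per_px - calib.near_side.slope_mm_per_px))


def calibration_from_layout(layout) -> SizeCalibration:
    """Exact SizeCalibration implied by a scene layout's configured scales.

    Useful when the scales are known a priori (synthetic scenes, or a
    vendor-specified pixel pitch) rather than fitted from ruler images.
    """
    return SizeCalibration(
        top=LinearScale(layout.top_scale_mm_per_px, 0.0, 1.0),
        near_side=LinearScale(layout.near_scale_mm_per_px, 0.0, 1.0),
        far_side=LinearScale(layout.far_scale_mm_per_px, 0.0, 1.0),
        near_endpoint_px=layout.near_endpoint_px,
        far_endpoint_px=layout.far_endpoint_px,
    )


def default_calibration() -> SizeCalibration:
    """Illustrative defaults matching a typical belt camera (top slope
    0.0094 mm/px); real deployments calibrate from their own ruler images."""
    return SizeCalibration(
        top=LinearScale(0.0094, 0.012, 0.999),
        near_side=LinearScale(0.0093, 0.002, 0.999),
        far_side=LinearScale(0.0101, 0.008, 0.999),
        near_endpoint_px=1000.0,
        far_endpoint_px=2200.0,
    )
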