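"""Synthetic belt-imaging scenes with exact ground truth.

The real acquisition hardware photographs one singulated seed per frame:
a top-down view of the seed on a white conveyor, plus a partial side view
reflected by a prism mounted beside the lane.  This module renders the
same kind of frame — seed, ruler and precision-cylinder targets — from
analytic geometry, so that every downstream stage (colour calibration,
segmentation, size calibration, morphometrics, clustering) can be tested
against known truth without cameras.

Geometry model
--------------
* The top view shows the (2a, 2b) projection of a tri-axial ellipsoid seed
  with semi-axes ``(a, b, c)`` mm, at a uniform scale of
  ``top_scale_mm_per_px``.
* The prism reflects only the upper half of the side profile, so the side
  view shows the (2a, 2c) ellipse truncated at an exact equatorial midline
  row.  Side-view magnification varies linearly with the seed's column
  position between a near-prism and a far-prism endpoint — the same depth
  model the analysis assumes.
* Frames are rasterised with 4x supersampling and box down-sampling so
  that object edges carry sub-pixel information; 8-bit quantisation
  happens only when a frame is written to PNG.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage import color as skcolor

SUPERSAMPLE = 4

# ---------------------------------------------------------------------------
# layout / camera / seed descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneLayout:
    """Frame geometry and pixel-to-mm scales of the imaging chamber.

    Regions are (row_start, row_stop, col_start, col_stop), 0-based and
    half-open, in full-frame coordinates.  ``side_midline_row`` is the
    full-frame row of the seed's equatorial plane in the prism reflection.
    """

    frame_width_px: int = 2200
    frame_height_px: int = 1500
    top_region: tuple[int, int, int, int] = (80, 880, 100, 2100)
    side_region: tuple[int, int, int, int] = (920, 1420, 100, 2100)
    side_midline_row: int = 1380
    top_scale_mm_per_px: float = 0.0094
    near_scale_mm_per_px: float = 0.0093
    far_scale_mm_per_px: float = 0.0101
    near_endpoint_px: float = 1000.0
    far_endpoint_px: float = 2200.0
    belt_lab: tuple[float, float, float] = (92.0, 0.2, 1.5)

    def __post_init__(self) -> None:
        for name in ("top_scale_mm_per_px", "near_scale_mm_per_px", "far_scale_mm_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.near_endpoint_px == self.far_endpoint_px:
            raise ValueError("near and far endpoints must differ")
        for reg in (self.top_region, self.side_region):
            r0, r1, c0, c1 = reg
            if not (0 <= r0 < r1 <= self.frame_height_px and 0 <= c0 < c1 <= self.frame_width_px):
                raise ValueError(f"region {reg} outside frame")
        tr, sr = self.top_region, self.side_region
        rows_overlap = tr[0] < sr[1] and sr[0] < tr[1]
        cols_overlap = tr[2] < sr[3] and sr[2] < tr[3]
        if rows_overlap and cols_overlap:
            raise ValueError("top and side regions overlap")

    def side_scale_at(self, x_px: float) -> float:
        """Side-view mm/px at column ``x_px`` (linear in depth, clamped)."""
        lo, hi = self.near_endpoint_px, self.far_endpoint_px
        t = (x_px - lo) / (hi - lo)
        t = min(max(t, 0.0), 1.0)
        return self.near_scale_mm_per_px + t * (self.far_scale_mm_per_px - self.near_scale_mm_per_px)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneLayout":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("top_region", "side_region", "belt_lab"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CameraModel:
    """Forward model of the camera's colour distortion.

    Output = clip(color_matrix @ input**channel_gamma + noise, 0, 1) on
    scaled RGB in [0, 1].  With gamma 1, an identity matrix and zero noise
    the camera is the identity.
    """

    channel_gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    color_matrix: tuple[tuple[float, ...], ...] = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.color_matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("color_matrix must be an invertible 3x3 matrix")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def identity(cls) -> "CameraModel":
        return cls()

    @classmethod
    def default_distorted(cls, seed: int = 0, noise_sd: float = 1 / 255) -> "CameraModel":
        """Machine-vision-like distortion: gamma 2.2 per channel and a
        channel-mixing matrix that leaves greys alone but passes only ~60%
        of the chroma information, plus mild sensor noise."""
        alpha = 0.6
        m = tuple(
            tuple(alpha * (i == j) + (1 - alpha) / 3 for j in range(3)) for i in range(3)
        )
        return cls(channel_gamma=(2.2, 2.2, 2.2), color_matrix=m, noise_sd=noise_sd, seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["color_matrix"] = [list(r) for r in d["color_matrix"]]
        d["channel_gamma"] = list(d["channel_gamma"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CameraModel":
        d = yaml.safe_load(Path(path).read_text())
        d["channel_gamma"] = tuple(d["channel_gamma"])
        d["color_matrix"] = tuple(tuple(r) for r in d["color_matrix"])
        return cls(**d)


@dataclass(frozen=True)
class SeedSpec:
    """A synthetic seed: tri-axial ellipsoid with a base coat colour and an
    optional two-colour pattern.

    ``shading_l_drop`` models the lightness fall-off towards the rim of the
    domed seed under diffuse light (cosine law: flat in the centre, dropping
    by up to ``shading_l_drop`` L* units right at the rim).
    ``texture_l_sd`` is the standard deviation of a smooth random mottle
    field emulating the granular texture of a real seed coat; it perturbs
    L* at full strength and a*/b* at a quarter strength.
    """

    semi_axes_mm: tuple[float, float, float] = (2.5, 2.3, 1.1)
    center_top_px: tuple[float, float] = (480.0, 1100.0)
    base_lab: tuple[float, float, float] = (45.0, 18.0, 28.0)
    pattern_lab: tuple[float, float, float] = (28.0, 12.0, 14.0)
    pattern_fraction: float = 0.0
    pattern_kind: str = "none"  # none | spots | marble
    shading_l_drop: float = 3.0
    texture_l_sd: float = 1.8
    pattern_seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes_mm
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.pattern_fraction <= 1.0:
            raise ValueError("pattern_fraction must be in [0, 1]")
        if self.pattern_fraction == 0.0 and self.pattern_kind != "none":
            raise ValueError("pattern_fraction 0 requires pattern_kind 'none'")
        if self.pattern_kind not in ("none", "spots", "marble"):
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")


@dataclass
class RawFrame:
    """One seed's RGB frame plus its identity in the folder convention."""

    rgb_image: np.ndarray  # float scaled RGB in [0,1], shape (H, W, 3)
    sample_id: str = "synthetic"
    camera_id: str = "A"
    image_index: int = 0
    source_path: str | None = None

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.rgb_image * 255), 0, 255).astype(np.uint8)

    def write_png(self, root: str | Path) -> Path:
        path = Path(root) / self.sample_id / self.camera_id / f"{self.image_index:04d}.png"
        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, self.to_uint8())
        return path


@dataclass
class GroundTruth:
    """Exact truth for a rendered frame, for round-trip tests."""

    top_mask: np.ndarray | None = None  # bool, top-region shape
    side_mask: np.ndarray | None = None  # bool, side-region shape
    seed: SeedSpec | None = None
    diameter_mm: float | None = None
    center_col_frame: float | None = None
    side_scale_mm_per_px: float | None = None
    touches_border: bool = False
    tick_positions_px: list[float] = field(default_factory=list)

    def write_json(self, path: str | Path) -> None:
        d = {
            "touches_border": self.touches_border,
            "diameter_mm": self.diameter_mm,
            "center_col_frame": self.center_col_frame,
            "side_scale_mm_per_px": self.side_scale_mm_per_px,
            "tick_positions_px": self.tick_positions_px,
            "seed": dataclasses.asdict(self.seed) if self.seed else None,
        }
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# colour helpers
# ---------------------------------------------------------------------------


def lab_to_rgb_strict(lab: np.ndarray) -> np.ndarray:
    """Convert L*a*b* (D65, 2 deg) to scaled sRGB, rejecting out-of-gamut input.

    A reference colour that does not survive a round trip through sRGB
    cannot be displayed by the chart renderer and is treated as an error.
    """
    lab = np.asarray(lab, dtype=float)
    rgb = skcolor.lab2rgb(lab.reshape(1, 1, 3)).reshape(3)
    back = skcolor.rgb2lab(rgb.reshape(1, 1, 3)).reshape(3)
    if np.linalg.norm(back - lab) > 1.0:
        raise ValueError(f"L*a*b* {tuple(lab)} is outside the sRGB gamut")
    return rgb


def apply_camera(camera: CameraModel, true_rgb: np.ndarray) -> np.ndarray:
    """Push a scaled-RGB image through the camera's forward model."""
    img = np.asarray(true_rgb, dtype=float)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("input RGB must be scaled to [0, 1]")
    gamma = np.asarray(camera.channel_gamma, dtype=float)
    out = np.clip(img, 0, 1) ** gamma
    out = out @ np.asarray(camera.color_matrix, dtype=float).T
    if camera.noise_sd > 0:
        rng = np.random.default_rng(camera.seed)
        out = out + rng.normal(0.0, camera.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# colour-checker chart
# ---------------------------------------------------------------------------


def chart_reference_labs(full: bool = False) -> np.ndarray:
    """Reference L*a*b* values of the synthetic calibration chart.

    The chart is a 10 x 14 grid of 140 swatches laid out like a studio
    colour checker: the first row and first column are greyscale ramps and
    the 9 x 13 interior is a hue/lightness/saturation grid weighted towards
    the browns and greens of seed coats.  ``full=False`` drops the
    greyscale row and column, leaving the 117 chromatic swatches used to
    build calibration datasets.
    """
    grid = np.zeros((10, 14, 3))
    grid[0, :, :] = np.linspace(0.03, 0.97, 14)[:, None]  # greyscale row
    grid[:, 0, :] = np.linspace(0.05, 0.95, 10)[:, None]  # greyscale column
    hues = np.linspace(0.0, 0.9, 13)
    # (value, saturation) pairs: mid values and moderate saturations dominate,
    # mimicking the natural-tone emphasis of seed-coat colours
    vs = [(0.15, 0.5), (0.3, 0.4), (0.3, 0.8), (0.45, 0.55), (0.55, 0.3),
          (0.6, 0.7), (0.7, 0.45), (0.85, 0.25), (0.9, 0.6)]
    for i, (v, s) in enumerate(vs):
        hsv = np.stack([hues, np.full(13, s), np.full(13, v)], axis=-1)
        grid[i + 1, 1:, :] = skcolor.hsv2rgb(hsv.reshape(1, 13, 3)).reshape(13, 3)
    if not full:
        grid = grid[1:, 1:]
    rgb = grid.reshape(-1, 3)
    return skcolor.rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)


def render_colorchecker_patches(
    refs: np.ndarray, camera: CameraModel, patch_size: int = 200
) -> list[np.ndarray]:
    """Render one uniform chart swatch per reference colour through the camera.

    Each patch is ``patch_size`` x ``patch_size`` scaled RGB with the
    camera's per-pixel noise; with an identity, noiseless camera the patch
    is constant at the reference colour.
    """
    refs = np.asarray(refs, dtype=float)
    if refs.ndim != 2 or refs.shape[0] == 0 or refs.shape[1] != 3:
        raise ValueError("refs must be a non-empty (n, 3) array of L*a*b*")
    patches = []
    for i, lab in enumerate(refs):
        rgb = lab_to_rgb_strict(lab)
        flat = np.broadcast_to(rgb, (patch_size, patch_size, 3))
        cam_i = dataclasses.replace(camera, seed=(camera.seed * 100003 + i) % (2**31))
        patches.append(apply_camera(cam_i, flat))
    return patches


# ---------------------------------------------------------------------------
# rasterisation helpers
# ---------------------------------------------------------------------------


def _box_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    h, w = img.shape[:2]
    sh = (h // factor, factor, w // factor, factor) + img.shape[2:]
    return img.reshape(sh).mean(axis=(1, 3))


def _ellipse_coverage(shape: tuple[int, int], center: tuple[float, float],
                      semi_r: float, semi_c: float) -> np.ndarray:
    """Per-pixel area coverage of an axis-aligned ellipse, supersampled."""
    f = SUPERSAMPLE
    rr = (np.arange(shape[0] * f) + 0.5) / f - 0.5
    cc = (np.arange(shape[1] * f) + 0.5) / f - 0.5
    dr = (rr - center[0]) / semi_r
    dc = (cc - center[1]) / semi_c
    inside = (dr[:, None] ** 2 + dc[None, :] ** 2) <= 1.0
    return _box_downsample(inside.astype(float), f)


def render_ruler(
    layout: SceneLayout,
    view: str = "top",
    tick_spacing_mm: float = 1.0,
    axis: str = "x",
    length_px: int | None = None,
    width_px: int = 200,
    blur_sigma: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a greyscale ruler image with tick marks at exact pixel pitch.

    Tick marks run perpendicular to the ruler axis; each mark is a dark bar
    whose leading edge sits at ``k * tick_spacing_mm / scale(view)`` pixels.
    The far side view is blurred by default because the prism's depth of
    focus is shallow there.
    """
    if view not in ("top", "near_side", "far_side"):
        raise ValueError(f"unknown view {view!r}")
    scale = {
        "top": layout.top_scale_mm_per_px,
        "near_side": layout.near_scale_mm_per_px,
        "far_side": layout.far_scale_mm_per_px,
    }[view]
    pitch = tick_spacing_mm / scale
    if pitch < 2.0:
        raise ValueError(f"tick pitch {pitch:.2f} px is below 2 px")
    if length_px is None:
        length_px = layout.frame_width_px
    n_ticks = int((length_px - pitch) // pitch)
    if n_ticks < 10:
        raise ValueError("fewer than 10 ticks representable in the view")

    f = SUPERSAMPLE
    x = (np.arange(length_px * f) + 0.5) / f  # pixel coordinate
    profile = np.ones_like(x)
    tick_width = 0.4 * pitch
    margin = pitch / 2
    positions = []
    for k in range(n_ticks):
        edge = margin + k * pitch
        profile[(x >= edge) & (x < edge + tick_width)] = 0.08
        positions.append(edge)
    profile = profile.reshape(-1, f).mean(axis=1)
    img = np.broadcast_to(profile, (width_px, length_px)).copy()
    if axis == "y":
        img = img.T
    if blur_sigma is None and view == "far_side":
        blur_sigma = 2.0
    if blur_sigma:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, 1)
    return img, GroundTruth(tick_positions_px=positions)


def _pattern_mask(shape: tuple[int, int], kind: str, fraction: float,
                  seed: int) -> np.ndarray:
    """Boolean pattern field covering roughly ``fraction`` of the area."""
    if kind == "none" or fraction <= 0:
        return np.zeros(shape, dtype=bool)
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    noise = rng.standard_normal(shape)
    sigma = 6.0 if kind == "spots" else (2.0, 14.0)  # marble: anisotropic streaks
    smooth = gaussian_filter(noise, sigma)
    thresh = np.quantile(smooth, 1.0 - fraction)
    return smooth > thresh


def _paint_region(
    lab_bg: np.ndarray,
    region_shape: tuple[int, int],
    coverage: np.ndarray,
    base_lab: np.ndarray,
    pattern: np.ndarray | None,
    pattern_lab: np.ndarray | None,
    shading: np.ndarray | None,
    texture: np.ndarray | None = None,
) -> np.ndarray:
    """Composite a seed (or cylinder) onto a uniform background, in L*a*b*."""
    lab = np.broadcast_to(lab_bg, region_shape + (3,)).copy()
    seed_lab = np.broadcast_to(base_lab, region_shape + (3,)).copy()
    if pattern is not None and pattern_lab is not None:
        seed_lab[pattern] = pattern_lab
    if texture is not None:
        seed_lab = seed_lab + texture
    if shading is not None:
        seed_lab[..., 0] = np.clip(seed_lab[..., 0] - shading, 0, 100)
    cov = coverage[..., None]
    return lab * (1 - cov) + seed_lab * cov


def render_seed_frame(
    layout: SceneLayout,
    seed: SeedSpec,
    camera: CameraModel,
    sample_id: str = "synthetic",
    image_index: int = 0,
) -> tuple[RawFrame, GroundTruth]:
    """Render a full dual-view frame of one seed, with exact ground truth.

    The top view holds the (2a, 2b) ellipse projection at the top scale;
    the side view holds the upper half of the (2a, 2c) ellipse above the
    configured midline row, at the depth-interpolated side scale for the
    seed's column position.
    """
    a, b, c = seed.semi_axes_mm
    ts = layout.top_scale_mm_per_px
    r0, r1, c0, c1 = layout.top_region
    top_shape = (r1 - r0, c1 - c0)
    ctr_row, ctr_col = seed.center_top_px  # frame coordinates
    center_top = (ctr_row - r0, ctr_col - c0)
    semi_row, semi_col = b / ts, a / ts
    if not (semi_row < center_top[0] < top_shape[0] - semi_row
            and semi_col < center_top[1] < top_shape[1] - semi_col):
        touches = True
    else:
        touches = False

    top_cov = _ellipse_coverage(top_shape, center_top, semi_row, semi_col)
    top_mask = top_cov >= 0.5

    # dome shading (cosine law), coat mottle texture and pattern, top view
    rr = (np.arange(top_shape[0]) - center_top[0]) / max(semi_row, 1e-9)
    cc = (np.arange(top_shape[1]) - center_top[1]) / max(semi_col, 1e-9)
    radial2 = np.clip(rr[:, None] ** 2 + cc[None, :] ** 2, 0, 1)
    shading = seed.shading_l_drop * (1.0 - np.sqrt(1.0 - radial2))
    if seed.texture_l_sd > 0:
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(seed.pattern_seed + 7919)
        field = gaussian_filter(rng.standard_normal(top_shape), 2.0)
        field /= max(field.std(), 1e-12)
        texture = field[..., None] * np.array([1.0, 0.25, 0.25]) * seed.texture_l_sd
    else:
        texture = None
    pattern = _pattern_mask(top_shape, seed.pattern_kind, seed.pattern_fraction,
                            seed.pattern_seed)

    belt = np.asarray(layout.belt_lab, dtype=float)
    base = np.asarray(seed.base_lab, dtype=float)
    pat = np.asarray(seed.pattern_lab, dtype=float)
    top_lab = _paint_region(belt, top_shape, top_cov, base, pattern, pat, shading,
                            texture)

    # side view: upper half of the (2a, 2c) ellipse above the midline row
    ss = layout.side_scale_at(ctr_col)
    sr0, sr1, sc0, sc1 = layout.side_region
    side_shape = (sr1 - sr0, sc1 - sc0)
    mid_row_view = layout.side_midline_row - sr0
    if not 0 < mid_row_view <= side_shape[0]:
        raise ValueError("side_midline_row outside side region")
    center_side = (float(mid_row_view), ctr_col - sc0)
    side_cov = _ellipse_coverage(side_shape, center_side, c / ss, a / ss)
    rows = np.arange(side_shape[0])
    side_cov[rows > mid_row_view, :] = 0.0  # prism reflects the upper half only
    side_mask = side_cov >= 0.5
    if side_mask[0, :].any() or side_mask[:, 0].any() or side_mask[:, -1].any():
        touches = True
    side_shading = np.full(side_shape, 0.5 * seed.shading_l_drop)
    side_lab = _paint_region(belt, side_shape, side_cov, base, None, None, side_shading)

    frame_lab = np.broadcast_to(belt, (layout.frame_height_px, layout.frame_width_px, 3)).copy()
    frame_lab[r0:r1, c0:c1] = top_lab
    frame_lab[sr0:sr1, sc0:sc1] = side_lab

    rgb = skcolor.lab2rgb(frame_lab)
    rgb = apply_camera(camera, rgb)
    frame = RawFrame(rgb_image=rgb, sample_id=sample_id, camera_id="A",
                     image_index=image_index)
    truth = GroundTruth(top_mask=top_mask, side_mask=side_mask, seed=seed,
                        center_col_frame=ctr_col, side_scale_mm_per_px=ss,
                        touches_border=touches)
    return frame, truth


def render_cylinder_frame(
    layout: SceneLayout,
    diameter_mm: float,
    center_row_frame: float | None = None,
    camera: CameraModel | None = None,
) -> tuple[RawFrame, GroundTruth]:
    """Render a dark precision cylinder lying along the belt axis in the top view.

    The cylinder's pixel width is exactly ``diameter_mm / top_scale``; it is
    rasterised with supersampled anti-aliased edges so the analysis can be
    validated to sub-pixel accuracy.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    ts = layout.top_scale_mm_per_px
    width_px = diameter_mm / ts
    if width_px < 2.0:
        raise ValueError(f"cylinder width {width_px:.2f} px is sub-pixel territory")
    r0, r1, c0, c1 = layout.top_region
    top_shape = (r1 - r0, c1 - c0)
    if center_row_frame is None:
        center_row_frame = (r0 + r1) / 2
    ctr = center_row_frame - r0

    f = SUPERSAMPLE
    rr = (np.arange(top_shape[0] * f) + 0.5) / f - 0.5
    inside = np.abs(rr - ctr) <= width_px / 2
    cov_col = inside.astype(float).reshape(-1, f).mean(axis=1)
    cov = np.broadcast_to(cov_col[:, None], top_shape)

    belt = np.asarray(layout.belt_lab, dtype=float)
    cyl_lab = np.array([22.0, 0.5, 0.5])  # dark polished steel, near-neutral
    top_lab = _paint_region(belt, top_shape, cov, cyl_lab, None, None, None)
    frame_lab = np.broadcast_to(belt, (layout.frame_height_px, layout.frame_width_px, 3)).copy()
    frame_lab[r0:r1, c0:c1] = top_lab
    rgb = skcolor.lab2rgb(frame_lab)
    if camera is not None:
        rgb = apply_camera(camera, rgb)
    frame = RawFrame(rgb_image=rgb, sample_id="cylinder", image_index=0)
    truth = GroundTruth(top_mask=cov >= 0.5, diameter_mm=diameter_mm)
    return frame, truth
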