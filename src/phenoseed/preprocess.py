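"""Preprocessing: colour-calibrate a frame, segment both views, save intermediates.

The segmentation channel merges chroma and lightness information:

    M = scale01(|a*|) + scale01(|b*|) - 0.5 * scale01(L*)

where scale01 is per-view min-max normalisation (a constant channel maps
to zeros).  Coloured seeds stand out through |a*| and |b*|; dark neutral
seeds are still separable because the white belt carries the maximum L*
and therefore the most negative lightness term.  The merged image is
thresholded with Otsu's method, interior holes are filled, and the
largest connected component is kept.  A mask touching its view border
means the seed was not fully inside the crop (typically not fully
reflected in the prism) and the frame is rejected rather than measured.

Four items form the intermediate record of an accepted frame: the
calibrated L*a*b* crop, the top-view mask, the side-view mask, and the
column of the longest vertical run of the top mask (the depth proxy used
to scale side-view measurements).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import color as skcolor
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from scipy import ndimage

from .colorcal import ColorModel, apply_model
from .scene_synth import RawFrame, SceneLayout


@dataclass
class IntermediateRecord:
    """The per-seed preprocessing output (or a rejection with its reason)."""

    sample_id: str
    camera_id: str
    image_index: int
    lab_crop: np.ndarray | None = None
    top_mask: np.ndarray | None = None
    side_mask: np.ndarray | None = None
    midline_x_px: int | None = None  # column in full-frame coordinates
    crop_origin: tuple[int, int] = (0, 0)  # frame (row, col) of lab_crop[0, 0]
    rejected: str | None = None

    @property
    def ok(self) -> bool:
        return self.rejected is None

    def top_lab_pixels(self, layout: SceneLayout, erode_px: int = 2,
                       with_coords: bool = False):
        """Calibrated L*a*b* values of the top-view seed pixels, (n, 3).

        The mask is eroded by ``erode_px`` before extraction so that
        anti-aliased boundary pixels — a thin ring of seed/belt colour
        mixtures — do not contaminate the coat-colour distribution.  The
        lab crop is stored at the top-view seed bounding box; this maps
        the top-mask coordinates into the crop.
        """
        if not self.ok:
            raise ValueError("record was rejected; no seed pixels")
        mask = self.top_mask
        if erode_px > 0:
            eroded = ndimage.binary_erosion(mask, iterations=erode_px)
            if eroded.any():  # tiny seeds keep the full mask
                mask = eroded
        rr, cc = np.nonzero(mask)
        r = rr + layout.top_region[0] - self.crop_origin[0]
        c = cc + layout.top_region[2] - self.crop_origin[1]
        pixels = self.lab_crop[r, c].astype(float)
        if with_coords:
            return pixels, rr, cc
        return pixels

    # -- disk round trip -----------------------------------------------------

    def save(self, root: str | Path) -> Path:
        base = Path(root) / self.sample_id / self.camera_id
        base.mkdir(parents=True, exist_ok=True)
        stem = base / f"{self.image_index:04d}"
        meta = {
            "sample_id": self.sample_id,
            "camera_id": self.camera_id,
            "image_index": self.image_index,
            "midline_x_px": self.midline_x_px,
            "crop_origin": list(self.crop_origin),
            "rejected": self.rejected,
        }
        if self.ok:
            tifffile.imwrite(f"{stem}_lab.tif", self.lab_crop.astype(np.float32),
                             photometric="rgb")
            iio.imwrite(f"{stem}_topmask.png",
                        (self.top_mask.astype(np.uint8)) * 255)
            iio.imwrite(f"{stem}_sidemask.png",
                        (self.side_mask.astype(np.uint8)) * 255)
        Path(f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))
        return Path(f"{stem}_meta.json")

    @classmethod
    def load(cls, meta_path: str | Path) -> "IntermediateRecord":
        meta_path = Path(meta_path)
        meta = json.loads(meta_path.read_text())
        stem = str(meta_path)[: -len("_meta.json")]
        rec = cls(meta["sample_id"], meta["camera_id"], meta["image_index"],
                  midline_x_px=meta["midline_x_px"],
                  crop_origin=tuple(meta["crop_origin"]),
                  rejected=meta["rejected"])
        if rec.ok:
            rec.lab_crop = tifffile.imread(f"{stem}_lab.tif")
            rec.top_mask = iio.imread(f"{stem}_topmask.png") > 127
            rec.side_mask = iio.imread(f"{stem}_sidemask.png") > 127
        return rec


def rgb_to_lab(rgb_image: np.ndarray) -> np.ndarray:
    """Uncalibrated sRGB -> L*a*b* conversion (D65, 2 deg observer)."""
    return skcolor.rgb2lab(np.asarray(rgb_image, dtype=float))


def crop_views(lab_frame: np.ndarray, layout: SceneLayout) -> tuple[np.ndarray, np.ndarray]:
    """Cut the top (conveyor) and side (prism reflection) views out of a frame."""
    h, w = lab_frame.shape[:2]
    for reg in (layout.top_region, layout.side_region):
        r0, r1, c0, c1 = reg
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"region {reg} outside frame of shape {(h, w)}")
    r0, r1, c0, c1 = layout.top_region
    top = lab_frame[r0:r1, c0:c1]
    r0, r1, c0, c1 = layout.side_region
    side = lab_frame[r0:r1, c0:c1]
    return top, side


def _scale01(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def merged_channel(lab_view: np.ndarray) -> np.ndarray:
    """The segmentation channel: chroma magnitudes minus half the lightness."""
    L, a, b = lab_view[..., 0], lab_view[..., 1], lab_view[..., 2]
    return _scale01(np.abs(a)) + _scale01(np.abs(b)) - 0.5 * _scale01(L)


def seed_mask(merged: np.ndarray) -> np.ndarray:
    """Otsu-threshold the merged channel, fill holes, keep the largest object.

    Foreground uses 8-connectivity (background implicitly 4-connected).
    The Otsu threshold is computed on a 256-bin histogram after affine
    rescale of the merged image to [0, 1].
    """
    merged = np.asarray(merged, dtype=float)
    if np.ptp(merged) == 0:
        raise ValueError("constant merged image: nothing to segment")
    scaled = (merged - merged.min()) / np.ptp(merged)
    t = threshold_otsu(scaled, nbins=256)
    binary = scaled > t
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise ValueError("empty mask after thresholding")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def border_valid(mask: np.ndarray, view_shape: tuple[int, int] | None = None) -> bool:
    """True iff no mask pixel lies on the outer border of its view."""
    if view_shape is not None and mask.shape != tuple(view_shape):
        raise ValueError("mask shape does not match view shape")
    return not (mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


def longest_vertical_x(top_mask: np.ndarray) -> int:
    """Column with the longest vertical run of mask pixels.

    For a convex seed mask the per-column pixel count equals the longest
    vertical run, and its argmax is the seed's midline column — the proxy
    for the seed's distance to the prism.  At pixel resolution the argmax
    is a plateau (the flat top of the ellipse), so the lower median of the
    maximal columns is returned: the plateau centre for a symmetric mask,
    deterministic for any tie pattern.
    """
    if not top_mask.any():
        raise ValueError("empty mask")
    counts = top_mask.sum(axis=0)
    best = np.nonzero(counts == counts.max())[0]
    return int(best[(len(best) - 1) // 2])


def preprocess_frame(
    frame: RawFrame,
    model: ColorModel | None,
    layout: SceneLayout,
) -> IntermediateRecord:
    """Full preprocessing chain for one frame.

    Calibrates to L*a*b* (plain sRGB conversion if no colour model is
    supplied), crops both views, segments each, applies the border checks,
    and locates the depth-proxy column.  Failed checks return a rejection
    record naming the stage; they never raise.
    """
    rec = IntermediateRecord(frame.sample_id, frame.camera_id, frame.image_index)
    if model is not None and model.camera_id != frame.camera_id:
        import warnings
        warnings.warn(f"colour model for camera {model.camera_id!r} applied to "
                      f"frame from camera {frame.camera_id!r}")
    lab = apply_model(model, frame.rgb_image) if model is not None \
        else rgb_to_lab(frame.rgb_image)
    top_view, side_view = crop_views(lab, layout)

    for name, view in (("top", top_view), ("side", side_view)):
        try:
            mask = seed_mask(merged_channel(view))
        except ValueError:
            rec.rejected = f"segmentation_{name}"
            return rec
        if not border_valid(mask):
            rec.rejected = f"border_{name}"
            return rec
        if name == "top":
            top_mask = mask
        else:
            side_mask = mask

    rec.top_mask = top_mask
    rec.side_mask = side_mask
    rec.midline_x_px = longest_vertical_x(top_mask) + layout.top_region[2]

    # calibrated L*a*b* crop: bounding box of the top-view seed (plus a
    # 4 px margin), in full-frame coordinates.  Only top-view colour feeds
    # the downstream statistics; the side view contributes geometry through
    # its mask, so storing the inter-view gap would defeat the crop.
    tr0, tr1, tc0, tc1 = layout.top_region
    rr, cc = np.nonzero(top_mask)
    r0 = max(rr.min() + tr0 - 4, tr0)
    r1 = min(rr.max() + tr0 + 5, tr1)
    c0 = max(cc.min() + tc0 - 4, tc0)
    c1 = min(cc.max() + tc0 + 5, tc1)
    rec.lab_crop = lab[r0:r1, c0:c1].astype(np.float32)
    rec.crop_origin = (int(r0), int(c0))
    return rec
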