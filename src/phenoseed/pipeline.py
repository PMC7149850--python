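"""Batch orchestration over the belt folder convention.

Frames live at ``<input_root>/<sampleID>/<camera>/<index>.png``.  Each
frame is preprocessed (colour calibration + dual-view segmentation) into
an intermediate record, then measured (morphometrics, colour statistics,
coat clustering) into one row of the results table.  Preprocessing is
skippable when intermediates already exist on disk, so new measurement
code can be re-run cheaply.

Every seed gets its own RNG seed derived deterministically from the base
seed and the frame identity, so results are bit-identical regardless of
worker count or scheduling order.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from multiprocessing import Pool
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import coat_color, morphometry
from .colorcal import ColorModel
from .preprocess import IntermediateRecord, preprocess_frame
from .scene_synth import RawFrame, SceneLayout
from .sizecal import SizeCalibration, default_calibration

_FRAME_RE = re.compile(r"^\d+\.png$")

RESULT_COLUMNS = [
    "sample_id", "camera_id", "image_index", "status",
    "major_axis_mm", "minor_axis_mm", "height_mm", "area_mm2", "perimeter_mm",
    "volume_mm3", "surface_area_mm2", "roundness", "circularity", "sphericity",
    "major_axis_px", "minor_axis_px", "height_px", "area_px", "perimeter_px",
    "L_mean", "L_min", "L_max", "L_sd",
    "a_mean", "a_min", "a_max", "a_sd",
    "b_mean", "b_min", "b_max", "b_sd",
    "cluster_method", "cluster_distance_de2000",
    "cluster_pop_1", "cluster_pop_2", "gmm_avg_log_likelihood",
    "pattern_call", "rng_seed",
]


@dataclass
class RunConfig:
    """Everything a batch run needs."""

    input_root: Path
    output_root: Path
    layout: SceneLayout = field(default_factory=SceneLayout)
    color_model_paths: dict[str, str] = field(default_factory=dict)
    size_calibration: SizeCalibration = field(default_factory=default_calibration)
    workers: int = 16
    rng_seed_base: int = 0
    skip_preprocess: bool = False
    write_labelmaps: bool = False
    comparison_kmeans: bool = False

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def derive_seed(base: int, sample_id: str, camera_id: str, image_index: int) -> int:
    """Stable per-seed RNG seed, independent of scheduling (always < 2^31)."""
    key = f"{base}:{sample_id}:{camera_id}:{image_index}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def discover(input_root: str | Path) -> list[dict]:
    """Find all frames under the folder convention, in lexicographic order.

    Returns one record per ``<sampleID>/<camera>/<index>.png``; files that
    do not match the convention are skipped with a warning.
    """
    root = Path(input_root)
    if not root.is_dir():
        raise FileNotFoundError(f"input root {root} does not exist")
    records = []
    for path in root.rglob("*"):
        if not path.is_file():
            continue
        rel = path.relative_to(root)
        if len(rel.parts) == 3 and _FRAME_RE.match(rel.parts[2]):
            records.append({
                "sample_id": rel.parts[0],
                "camera_id": rel.parts[1],
                "image_index": int(rel.parts[2].split(".")[0]),
                "path": str(path),
            })
        elif path.suffix != ".json":  # JSON sidecars (ground truth) pass silently
            import warnings
            warnings.warn(f"skipping unrecognised file {rel}")
    if not records:
        raise FileNotFoundError(f"no frames found under {root}")
    records.sort(key=lambda r: (r["sample_id"], r["camera_id"], r["image_index"]))
    return records


def load_frame(record: dict) -> RawFrame:
    img = iio.imread(record["path"])
    return RawFrame(rgb_image=img[..., :3].astype(float) / 255.0,
                    sample_id=record["sample_id"], camera_id=record["camera_id"],
                    image_index=record["image_index"], source_path=record["path"])


def write_labelmap(rec: IntermediateRecord, labels: np.ndarray,
                   rows: np.ndarray, cols: np.ndarray, path: Path) -> None:
    """Cluster-label overlay PNG: background red, the two clusters blue/green."""
    img = np.zeros(rec.top_mask.shape + (3,), dtype=np.uint8)
    img[...] = (200, 40, 40)
    palette = np.array([(60, 90, 200), (70, 180, 90)], dtype=np.uint8)
    img[rows, cols] = palette[labels]
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img[max(r0 - 4, 0):r1 + 4, max(c0 - 4, 0):c1 + 4])


def measure_record(
    rec: IntermediateRecord,
    layout: SceneLayout,
    calib: SizeCalibration,
    seed: int,
    comparison_kmeans: bool = False,
    labelmap_path: Path | None = None,
) -> dict:
    """Main processing of one intermediate record into a results row."""
    row = {"sample_id": rec.sample_id, "camera_id": rec.camera_id,
           "image_index": rec.image_index, "rng_seed": seed}
    if not rec.ok:
        row["status"] = f"rejected:{rec.rejected}"
        return row
    row["status"] = "ok"
    midline_row = layout.side_midline_row - layout.side_region[0]
    shape = morphometry.measure_seed(rec.top_mask, rec.side_mask, midline_row,
                                     calib, rec.midline_x_px)
    for key in ("major_axis_px", "minor_axis_px", "height_px", "area_px",
                "perimeter_px", "major_axis_mm", "minor_axis_mm", "height_mm",
                "area_mm2", "perimeter_mm", "volume_mm3", "surface_area_mm2",
                "roundness", "circularity", "sphericity"):
        row[key] = getattr(shape, key)

    pixels, rr, cc = rec.top_lab_pixels(layout, with_coords=True)
    stats = coat_color.color_stats(pixels)
    for i, ch in enumerate("Lab"):
        row[f"{ch}_mean"] = stats.mean[i]
        row[f"{ch}_min"] = stats.minimum[i]
        row[f"{ch}_max"] = stats.maximum[i]
        row[f"{ch}_sd"] = stats.sd[i]

    sample = coat_color.subsample_pixels(pixels, rng_seed=seed)
    fit = coat_color.fit_kmeans2 if comparison_kmeans else coat_color.fit_gmm2
    model = fit(sample, seed)
    report = coat_color.cluster_report(model, pixels, seed)
    if labelmap_path is not None:
        write_labelmap(rec, model.predict(pixels), rr, cc, labelmap_path)
    row["cluster_method"] = report.method
    row["cluster_distance_de2000"] = report.centre_distance
    row["cluster_pop_1"], row["cluster_pop_2"] = report.populations
    row["gmm_avg_log_likelihood"] = report.avg_log_likelihood
    row["pattern_call"] = (coat_color.classify_pattern(report)
                           if report.method == "gmm" else "")
    return row


def _process_one(args) -> dict:
    record, config, models = args
    seed = derive_seed(config.rng_seed_base, record["sample_id"],
                       record["camera_id"], record["image_index"])
    inter_root = Path(config.output_root) / "intermediate"
    meta_path = (inter_root / record["sample_id"] / record["camera_id"]
                 / f"{record['image_index']:04d}_meta.json")
    if config.skip_preprocess and meta_path.exists():
        rec = IntermediateRecord.load(meta_path)
    else:
        frame = load_frame(record)
        model = models.get(record["camera_id"])
        rec = preprocess_frame(frame, model, config.layout)
        rec.save(inter_root)
    labelmap_path = None
    if config.write_labelmaps and rec.ok:
        labelmap_path = (Path(config.output_root) / "labelmaps"
                         / record["sample_id"] / record["camera_id"]
                         / f"{record['image_index']:04d}_labels.png")
    return measure_record(rec, config.layout, config.size_calibration, seed,
                          config.comparison_kmeans, labelmap_path)


def run(config: RunConfig) -> pd.DataFrame:
    """Run the batch: discover, (pre)process, measure, and return the table.

    A failing frame becomes a rejected row; missing colour models for a
    discovered camera abort before any work when model paths are given.
    """
    records = discover(config.input_root)
    models: dict[str, ColorModel] = {}
    for cam, path in config.color_model_paths.items():
        models[cam] = ColorModel.load(path)
    if config.color_model_paths:
        cameras = {r["camera_id"] for r in records}
        missing = cameras - set(models)
        if missing:
            raise FileNotFoundError(f"no colour model for camera(s) {sorted(missing)}")

    tasks = [(r, config, models) for r in records]
    if config.workers == 1 or len(tasks) == 1:
        rows = [_process_one(t) for t in tasks]
    else:
        with Pool(config.workers) as pool:
            rows = pool.map(_process_one, tasks)
    rows.sort(key=lambda r: (r["sample_id"], r["camera_id"], r["image_index"]))
    df = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RESULT_COLUMNS]


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-seed results table (full float precision, fixed columns)."""
    if len(df) == 0:
        raise ValueError("no rows to write")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def write_summary(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Per-sample aggregate: median / quartiles / IQR-outlier counts per metric.

    Rejected frames are tallied in a ``rejected`` column; no outlier is
    removed from the data, only counted.
    """
    if len(df) == 0:
        raise ValueError("no rows to summarise")
    metrics = ["major_axis_mm", "minor_axis_mm", "height_mm", "area_mm2",
               "volume_mm3", "roundness", "circularity", "sphericity",
               "L_mean", "a_mean", "b_mean", "cluster_distance_de2000"]
    out = []
    for sample, grp in df.groupby("sample_id"):
        ok = grp[grp["status"] == "ok"]
        row = {"sample_id": sample, "n_frames": len(grp), "n_ok": len(ok),
               "rejected": int((grp["status"] != "ok").sum())}
        for m in metrics:
            vals = ok[m].dropna().to_numpy()
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            outliers = int(((vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)).sum())
            row[f"{m}_median"] = med
            row[f"{m}_q1"] = q1
            row[f"{m}_q3"] = q3
            row[f"{m}_outliers"] = outliers
        out.append(row)
    summary = pd.DataFrame(out)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(path, index=False, float_format="%.12g")
    return summary
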