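"""Shared fixtures: synthetic scenes and trained calibration models.

Heavy artefacts (rendered frames, trained colour models) are session-scoped
so each is built once.  Pipeline tests use a half-resolution layout so that
multi-frame batches stay fast; single-frame fixtures use the full-size
default layout.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from phenoseed import colorcal, preprocess, scene_synth
from phenoseed.scene_synth import CameraModel, SceneLayout, SeedSpec


@pytest.fixture(scope="session")
def layout() -> SceneLayout:
    return SceneLayout()


@pytest.fixture(scope="session")
def small_layout() -> SceneLayout:
    """Half-resolution analogue of the default geometry (4x fewer pixels)."""
    return SceneLayout(
        frame_width_px=1100, frame_height_px=750,
        top_region=(40, 440, 50, 1050),
        side_region=(460, 710, 50, 1050),
        side_midline_row=690,
        top_scale_mm_per_px=0.0188,
        near_scale_mm_per_px=0.0186,
        far_scale_mm_per_px=0.0202,
        near_endpoint_px=500.0, far_endpoint_px=1100.0,
    )


@pytest.fixture(scope="session")
def identity_camera() -> CameraModel:
    return CameraModel.identity()


@pytest.fixture(scope="session")
def noisy_camera() -> CameraModel:
    return CameraModel(noise_sd=1 / 255, seed=3)


@pytest.fixture(scope="session")
def distorted_camera() -> CameraModel:
    return CameraModel.default_distorted(seed=0)


def _render_and_preprocess(layout, spec, camera):
    frame, truth = scene_synth.render_seed_frame(layout, spec, camera)
    rec = preprocess.preprocess_frame(frame, None, layout)
    return frame, truth, rec


@pytest.fixture(scope="session")
def single_seed(layout, noisy_camera):
    """Nominal single-colour brown lentil: (frame, truth, record)."""
    return _render_and_preprocess(layout, SeedSpec(), noisy_camera)


@pytest.fixture(scope="session")
def patterned_seed(layout, noisy_camera):
    """Spotted two-colour seed, 40% pattern coverage."""
    spec = SeedSpec(pattern_fraction=0.4, pattern_kind="spots", pattern_seed=5)
    return _render_and_preprocess(layout, spec, noisy_camera)


@pytest.fixture(scope="session")
def dark_seed(layout, identity_camera):
    """Dark low-chroma seed coat (the hard case for chroma-only segmentation)."""
    spec = SeedSpec(base_lab=(18.0, 2.0, 3.0), texture_l_sd=0.8)
    return _render_and_preprocess(layout, spec, identity_camera)


@pytest.fixture(scope="session")
def chart_refs_full() -> np.ndarray:
    return scene_synth.chart_reference_labs(full=True)


@pytest.fixture(scope="session")
def chart_refs() -> np.ndarray:
    return scene_synth.chart_reference_labs(full=False)


@pytest.fixture(scope="session")
def distorted_color_model(chart_refs_full, distorted_camera) -> colorcal.ColorModel:
    """MLPR + linear baseline trained on the distorted synthetic camera."""
    patches = scene_synth.render_colorchecker_patches(chart_refs_full, distorted_camera)
    return colorcal.train_color_model(patches, chart_refs_full, "A", rng_seed=0)


@pytest.fixture(scope="session")
def identity_color_model(chart_refs_full, identity_camera) -> colorcal.ColorModel:
    """Model trained on noiseless identity-camera patches (learnability check)."""
    patches = scene_synth.render_colorchecker_patches(chart_refs_full, identity_camera)
    return colorcal.train_color_model(patches, chart_refs_full, "A", rng_seed=0)


@pytest.fixture(scope="session")
def small_batch_dir(tmp_path_factory, small_layout):
    """A small on-disk batch: 2 samples x 3 frames, one border-rejected."""
    root = tmp_path_factory.mktemp("frames")
    camera = CameraModel(noise_sd=1 / 255, seed=1)
    specs = {
        "SAMP01": [
            SeedSpec(center_top_px=(240, 400), pattern_seed=1),
            SeedSpec(center_top_px=(240, 700), semi_axes_mm=(2.8, 2.5, 1.2),
                     pattern_seed=2),
            # c too tall for the side crop -> side mask touches the border
            SeedSpec(center_top_px=(240, 550), semi_axes_mm=(2.5, 2.3, 4.4),
                     pattern_seed=3),
        ],
        "SAMP02": [
            SeedSpec(center_top_px=(240, 500), base_lab=(55.0, 10.0, 30.0),
                     pattern_seed=4),
            SeedSpec(center_top_px=(240, 800), pattern_fraction=0.35,
                     pattern_kind="spots", pattern_seed=5),
            SeedSpec(center_top_px=(240, 300), semi_axes_mm=(2.2, 2.0, 1.0),
                     pattern_seed=6),
        ],
    }
    for sample, seed_specs in specs.items():
        for i, spec in enumerate(seed_specs):
            frame, _ = scene_synth.render_seed_frame(
                small_layout, spec, dataclasses.replace(camera, seed=camera.seed + i),
                sample_id=sample, image_index=i)
            frame.write_png(root)
    return root
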