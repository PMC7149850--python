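"""Colour calibration: dataset construction, models, and colour differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.color import lab2rgb, rgb2lab

from phenoseed import colorcal as cc
from phenoseed import scene_synth as ss

# Worked-example verification pairs published with the CIEDE2000 standard
# (reference Lab_1, Lab_2, expected dE00)
CIEDE2000_PAIRS = [
    ((50.0, 2.6772, -79.7751), (50.0, 0.0, -82.7485), 2.0425),
    ((50.0, 3.1571, -77.2803), (50.0, 0.0, -82.7485), 2.8615),
    ((50.0, 2.8361, -74.0200), (50.0, 0.0, -82.7485), 3.4412),
    ((50.0, -1.3802, -84.2814), (50.0, 0.0, -82.7485), 1.0000),
    ((50.0, -1.1848, -84.8006), (50.0, 0.0, -82.7485), 1.0000),
    ((50.0, -0.9009, -85.5211), (50.0, 0.0, -82.7485), 1.0000),
    ((50.0, 0.0, 0.0), (50.0, -1.0, 2.0), 2.3669),
    ((50.0, 2.49, -0.001), (50.0, -2.49, 0.0009), 7.1792),
    ((50.0, 2.5, 0.0), (73.0, 25.0, -18.0), 27.1492),
    ((50.0, 2.5, 0.0), (61.0, -5.0, 29.0), 22.8977),
    ((50.0, 2.5, 0.0), (56.0, -27.0, -3.0), 31.9030),
    ((50.0, 2.5, 0.0), (58.0, 24.0, 15.0), 19.4535),
    ((60.2574, -34.0099, 36.2677), (60.4626, -34.1751, 39.4387), 1.2644),
    ((63.0109, -31.0961, -5.8663), (62.8187, -29.7946, -4.0864), 1.2630),
    ((35.0831, -44.1164, 3.7933), (35.0232, -40.0716, 1.5901), 1.8645),
    ((22.7233, 20.0904, -46.6940), (23.0331, 14.9730, -42.5619), 2.0373),
    ((36.4612, 47.8580, 18.3852), (36.2715, 50.5065, 21.2231), 1.4146),
    ((90.8027, -2.0831, 1.4410), (91.1528, -1.6435, 0.0447), 1.4441),
    ((90.9257, -0.5406, -0.9208), (88.6381, -0.8985, -0.7239), 1.5381),
    ((6.7747, -0.2908, -2.4247), (5.8714, -0.0985, -2.2286), 0.6377),
    ((2.0776, 0.0795, -1.1350), (0.9033, -0.0636, -0.5514), 0.9082),
]


class TestPatchMedians:
    def test_constant_patch_gives_50_copies(self):
        patch = np.full((200, 200, 3), 0.37)
        med = cc.extract_patch_medians(patch)
        assert med.shape == (50, 3)
        np.testing.assert_allclose(med, 0.37)

    def test_regions_tile_patch_exactly(self):
        # paint each of the 10x5 blocks of 20x40 px with a distinct value;
        # the 50 medians must recover all block values: a perfect tiling of
        # 50 regions x 800 px = 40,000 px
        patch = np.zeros((200, 200, 3))
        k = 0
        for br in range(10):
            for bx in range(5):
                patch[br * 20:(br + 1) * 20, bx * 40:(bx + 1) * 40] = k / 50
                k += 1
        med = cc.extract_patch_medians(patch)
        np.testing.assert_allclose(med[:, 0], np.arange(50) / 50)
        assert 50 * 800 == 200 * 200

    def test_salt_noise_leaves_medians_unchanged(self):
        rng = np.random.default_rng(0)
        patch = np.full((200, 200, 3), 0.5)
        clean = cc.extract_patch_medians(patch)
        noisy = patch.copy()
        idx = rng.choice(200 * 200, size=400, replace=False)  # 1% of pixels
        noisy.reshape(-1, 3)[idx] = 1.0
        np.testing.assert_array_equal(cc.extract_patch_medians(noisy), clean)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            cc.extract_patch_medians(np.zeros((100, 200, 3)))


class TestDatasetBuildAndSplit:
    def test_117_patches_give_5850_samples(self, chart_refs):
        patches = [np.full((200, 200, 3), 0.5)] * 117
        ds = cc.build_dataset(patches, chart_refs)
        assert len(ds) == 5850

    def test_single_patch_gives_50_samples(self):
        ds = cc.build_dataset([np.full((200, 200, 3), 0.2)], np.array([[50.0, 0, 0]]))
        assert len(ds) == 50

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cc.build_dataset([], np.empty((0, 3)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cc.build_dataset([np.zeros((200, 200, 3))], np.zeros((2, 3)))

    def test_split_counts_and_partition(self, chart_refs):
        patches = [np.full((200, 200, 3), 0.5)] * 117
        ds = cc.build_dataset(patches, chart_refs)
        train, val, test = cc.split_dataset(ds, rng_seed=0)
        # floor(0.7 * 5850) = 4095 pool; floor(0.1 * 4095) = 409 validation
        assert len(val) == 409
        assert len(train) == 4095 - 409
        assert len(test) == 5850 - 4095
        assert len(train) + len(val) + len(test) == len(ds)

    def test_split_reproducible_and_disjoint(self):
        rng = np.random.default_rng(1)
        ds = cc.CalibrationDataset(rng.uniform(0, 1, (200, 3)),
                                   rng.uniform(0, 100, (200, 3)))
        a = cc.split_dataset(ds, rng_seed=7)
        b = cc.split_dataset(ds, rng_seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.rgb, y.rgb)
        # union of splits is the dataset (as a multiset of rows)
        union = np.vstack([s.rgb for s in a])
        assert union.shape == ds.rgb.shape
        assert {tuple(r) for r in union} == {tuple(r) for r in ds.rgb}

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        ds = cc.CalibrationDataset(rng.uniform(0, 1, (20, 3)),
                                   rng.uniform(0, 100, (20, 3)))
        ds.to_csv(tmp_path / "ds.csv")
        back = cc.CalibrationDataset.from_csv(tmp_path / "ds.csv")
        np.testing.assert_allclose(back.rgb, ds.rgb)
        np.testing.assert_allclose(back.ref_lab, ds.ref_lab)


class TestDeltaE:
    def test_identical_colours_zero(self):
        assert cc.delta_e76((50, 10, 10), (50, 10, 10)) == 0
        assert cc.delta_e2000((50, 10, 10), (50, 10, 10)) == 0

    def test_de76_345_triangle(self):
        assert cc.delta_e76((50, 0, 0), (50, 3, 4)) == pytest.approx(5.0)

    @pytest.mark.parametrize("lab1,lab2,expected", CIEDE2000_PAIRS)
    def test_ciede2000_published_worked_examples(self, lab1, lab2, expected):
        assert cc.delta_e2000(lab1, lab2) == pytest.approx(expected, abs=1e-4)
        assert cc.delta_e2000(lab2, lab1) == pytest.approx(expected, abs=1e-4)

    @given(st.lists(st.tuples(
        st.floats(0, 100), st.floats(-80, 80), st.floats(-80, 80)),
        min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_de76_is_a_metric(self, triples):
        x, y, z = (np.array(t) for t in triples)
        dxy = cc.delta_e76(x, y)
        assert dxy >= 0
        assert cc.delta_e76(x, x) == 0
        assert dxy == pytest.approx(cc.delta_e76(y, x))
        assert cc.delta_e76(x, z) <= dxy + cc.delta_e76(y, z) + 1e-9


class TestLinearModel:
    def test_exact_affine_map_recovered(self):
        rng = np.random.default_rng(3)
        true_rgb = rng.uniform(0.05, 0.95, (200, 3))
        M = np.array([[0.8, 0.1, 0.05], [0.05, 0.75, 0.1], [0.1, 0.05, 0.8]])
        off = np.array([0.02, -0.01, 0.03])
        measured = true_rgb @ M.T + off
        ds = cc.CalibrationDataset(measured,
                                   rgb2lab(true_rgb.reshape(1, -1, 3)).reshape(-1, 3))
        matrix, offset = cc.fit_linear_rgb(ds)
        recovered = cc.apply_linear_rgb(matrix, offset, measured)
        np.testing.assert_allclose(recovered, true_rgb, atol=1e-6)

    def test_identity_data_gives_identity_transform(self):
        rng = np.random.default_rng(4)
        rgb = rng.uniform(0.05, 0.95, (100, 3))
        ds = cc.CalibrationDataset(rgb, rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3))
        matrix, offset = cc.fit_linear_rgb(ds)
        np.testing.assert_allclose(matrix, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(offset, 0, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        rgb = np.tile([[0.5, 0.5, 0.5]], (10, 1))
        ds = cc.CalibrationDataset(rgb, np.tile([[50.0, 0, 0]], (10, 1)))
        with pytest.raises(ValueError, match="rank"):
            cc.fit_linear_rgb(ds)

    def test_too_few_samples_rejected(self):
        ds = cc.CalibrationDataset(np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cc.fit_linear_rgb(ds)


class TestMLPR:
    def test_identity_camera_learnable_below_de_1(self, identity_color_model):
        rep = identity_color_model.training_report["mlpr"]
        assert rep["mean_de2000"] < 1.0

    def test_distorted_camera_below_jnd(self, distorted_color_model):
        rep = distorted_color_model.training_report["mlpr"]
        assert rep["mean_de2000"] < 2.3

    def test_mlpr_beats_linear_beats_uncalibrated(self, distorted_color_model):
        rep = distorted_color_model.training_report
        assert (rep["mlpr"]["mean_de2000"] < rep["linear"]["mean_de2000"]
                < rep["uncalibrated"]["mean_de2000"])
        assert (rep["mlpr"]["mean_de76"] < rep["linear"]["mean_de76"]
                < rep["uncalibrated"]["mean_de76"])

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(5)
        rgb = rng.uniform(0, 1, (300, 3))
        lab = rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)
        train = cc.CalibrationDataset(rgb[:250], lab[:250])
        val = cc.CalibrationDataset(rgb[250:], lab[250:])
        m1, _ = cc.fit_mlpr(train, val, rng_seed=11, max_iter=200)
        m2, _ = cc.fit_mlpr(train, val, rng_seed=11, max_iter=200)
        np.testing.assert_array_equal(m1.predict(rgb), m2.predict(rgb))


class TestApplyAndEvaluate:
    def test_single_pixel_image_equals_direct_call(self, distorted_color_model):
        rgb = np.array([[[0.3, 0.4, 0.5]]])
        img_out = cc.apply_model(distorted_color_model, rgb)
        direct = distorted_color_model.mlpr.predict(rgb.reshape(1, 3))
        np.testing.assert_allclose(img_out.reshape(3), direct.reshape(3))

    def test_output_finite_on_coarse_rgb_grid(self, distorted_color_model):
        g = np.linspace(0, 1, 8)
        grid = np.stack(np.meshgrid(g, g, g), axis=-1).reshape(1, -1, 3)
        out = cc.apply_model(distorted_color_model, grid)
        assert np.isfinite(out).all()
        assert out[..., 0].min() >= 0 and out[..., 0].max() <= 100

    def test_evaluation_matches_brute_force_accumulation(
            self, distorted_color_model, chart_refs_full, distorted_camera):
        patches = ss.render_colorchecker_patches(chart_refs_full, distorted_camera)
        ds = cc.build_dataset(patches, chart_refs_full)
        _, _, test = cc.split_dataset(ds, rng_seed=0)
        report = cc.evaluate_calibration(distorted_color_model, test)
        preds = distorted_color_model.predict_lab(test.rgb)
        des = [float(cc.delta_e2000(test.ref_lab[i], preds[i]))
               for i in range(len(test))]
        assert report["mlpr"]["mean_de2000"] == pytest.approx(np.mean(des), rel=1e-9)
        assert report["mlpr"]["sd_de2000"] == pytest.approx(np.std(des), rel=1e-9)

    def test_model_serialisation_round_trip(self, distorted_color_model, tmp_path):
        distorted_color_model.save(tmp_path / "model")
        back = cc.ColorModel.load(tmp_path / "model")
        rng = np.random.default_rng(6)
        rgb = rng.uniform(0, 1, (50, 3))
        np.testing.assert_allclose(back.predict_lab(rgb),
                                   distorted_color_model.predict_lab(rgb))
        np.testing.assert_allclose(back.linear_matrix,
                                   distorted_color_model.linear_matrix)
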