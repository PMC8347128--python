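"""Preprocessing: squaring, bilinear resize, enhancement, augmentation, filtering."""

import numpy as np
import pytest

from aqua_ae.preprocess import (
    AugmentConfig,
    EnhanceConfig,
    PipelineConfig,
    augment,
    enhance,
    preprocess_pipeline,
    quality_filter,
    resize,
    sharpen_kernel,
    square_pad,
)
from aqua_ae.synth import SceneParams, compose_scene, save_scene


# ---- oracles ----

def oracle_bilinear(img, t):
    """Center-aligned bilinear interpolation with edge clamping."""
    h, w, c = img.shape
    out = np.zeros((t, t, c))
    for i in range(t):
        for j in range(t):
            y = (i + 0.5) * h / t - 0.5
            x = (j + 0.5) * w / t - 0.5
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            fy, fx = y - y0, x - x0
            ya, yb = np.clip([y0, y0 + 1], 0, h - 1)
            xa, xb = np.clip([x0, x0 + 1], 0, w - 1)
            out[i, j] = (
                (1 - fy) * (1 - fx) * img[ya, xa]
                + (1 - fy) * fx * img[ya, xb]
                + fy * (1 - fx) * img[yb, xa]
                + fy * fx * img[yb, xb]
            )
    return out


def oracle_enhance(img, cfg):
    """Step-by-step brute force: brightness, contrast, nested-loop correlation."""
    out = np.clip(img * cfg.brightness_factor, 0, 1)
    res = np.zeros_like(out)
    for c in range(3):
        mean = out[..., c].mean()
        res[..., c] = np.clip((out[..., c] - mean) * cfg.contrast_factor + mean, 0, 1)
    h, w, _ = img.shape
    filtered = np.zeros_like(res)
    for c in range(3):
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w:
                            acc += res[ii, jj, c] * cfg.kernel[di + 1, dj + 1]
                filtered[i, j, c] = acc
    return np.clip(filtered, 0, 1)


class TestSquarePad:
    def test_portrait_crop_pads_columns_evenly(self, rng):
        crop = rng.uniform(size=(100, 60, 3))
        out = square_pad(crop)
        assert out.shape == (100, 100, 3)
        assert not out[:, :20].any() and not out[:, 80:].any()
        np.testing.assert_array_equal(out[:, 20:80], crop)

    def test_square_input_unchanged(self, rng):
        crop = rng.uniform(size=(50, 50, 3))
        np.testing.assert_array_equal(square_pad(crop), crop)

    def test_landscape_centering_offset(self, rng):
        crop = rng.uniform(size=(3, 7, 3))
        out = square_pad(crop)
        assert out.shape == (7, 7, 3)
        np.testing.assert_array_equal(out[2:5, :], crop)  # floor((7-3)/2) = 2
        assert not out[:2].any() and not out[5:].any()

    def test_crop_back_recovers_original(self, rng):
        crop = rng.uniform(size=(9, 4, 3))
        out = square_pad(crop)
        y0, x0 = (9 - 9) // 2, (9 - 4) // 2
        np.testing.assert_array_equal(out[y0 : y0 + 9, x0 : x0 + 4], crop)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            square_pad(np.empty((0, 5, 3)))


class TestResize:
    def test_identity_when_already_target(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        np.testing.assert_array_equal(resize(img, 16), img)

    def test_constant_image_stays_constant(self):
        out = resize(np.full((8, 8, 3), 0.37), 5)
        np.testing.assert_allclose(out, 0.37)

    def test_checkerboard_matches_bilinear_oracle(self):
        board = np.zeros((2, 2, 3))
        board[0, 1] = board[1, 0] = 1.0
        np.testing.assert_allclose(resize(board, 4), oracle_bilinear(board, 4), atol=1e-12)

    @pytest.mark.parametrize("src,dst", [(4, 8), (8, 4), (5, 3)])
    def test_random_images_match_oracle(self, rng, src, dst):
        img = rng.uniform(size=(src, src, 3))
        np.testing.assert_allclose(resize(img, dst), oracle_bilinear(img, dst), atol=1e-12)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            resize(rng.uniform(size=(4, 4, 3)), 0)


class TestEnhance:
    def test_sum_one_kernel_preserves_constant_interior(self):
        cfg = EnhanceConfig(brightness_factor=1.0, contrast_factor=1.0,
                            kernel=sharpen_kernel(9.0))
        out = enhance(np.full((8, 8, 3), 0.2), cfg)
        np.testing.assert_allclose(out[1:-1, 1:-1], 0.2, atol=1e-12)

    def test_sum_three_kernel_triples_constant_interior(self):
        cfg = EnhanceConfig(brightness_factor=1.0, contrast_factor=1.0,
                            kernel=sharpen_kernel(11.0))
        out = enhance(np.full((8, 8, 3), 0.2), cfg)
        np.testing.assert_allclose(out[1:-1, 1:-1], 0.6, atol=1e-12)

    def test_default_config_matches_bruteforce_oracle(self, rng):
        img = rng.uniform(size=(8, 8, 3))
        cfg = EnhanceConfig()  # brightness 2, contrast 0.6, center-11 kernel
        np.testing.assert_allclose(enhance(img, cfg), oracle_enhance(img, cfg), atol=1e-12)

    def test_identity_configuration_is_identity(self, rng):
        ident = np.zeros((3, 3))
        ident[1, 1] = 1.0
        cfg = EnhanceConfig(brightness_factor=1.0, contrast_factor=1.0, kernel=ident)
        img = rng.uniform(size=(6, 6, 3))
        np.testing.assert_allclose(enhance(img, cfg), img, atol=1e-12)

    def test_non_3x3_kernel_rejected(self):
        with pytest.raises(ValueError):
            EnhanceConfig(kernel=np.ones((5, 5)))


class TestAugment:
    def test_eight_rotations_without_shifts(self, rng):
        out = augment(rng.uniform(size=(16, 16, 3)), AugmentConfig())
        assert len(out) == 8

    def test_right_angle_rotations_of_constant_are_identical(self):
        img = np.full((8, 8, 3), 0.4)
        out = augment(img, AugmentConfig(rotation_step_degrees=90.0))
        assert len(out) == 4
        for o in out:
            np.testing.assert_array_equal(o, img)

    @pytest.mark.parametrize("n_shifts,step,expected", [(3, 45.0, 32), (0, 90.0, 4), (2, 120.0, 9)])
    def test_count_formula(self, rng, n_shifts, step, expected):
        shifts = tuple((2.0 * k, -1.0 * k) for k in range(1, n_shifts + 1))
        out = augment(rng.uniform(size=(12, 12, 3)), AugmentConfig(step, shifts))
        assert len(out) == expected

    def test_quarter_turn_is_exact_index_permutation(self, rng):
        img = rng.uniform(size=(10, 10, 3))
        out = augment(img, AugmentConfig(rotation_step_degrees=90.0))
        np.testing.assert_array_equal(out[1], np.rot90(img, 1, axes=(0, 1)))

    def test_integer_shift_moves_content_with_zero_fill(self):
        img = np.zeros((8, 8, 3))
        img[3, 3] = 1.0
        out = augment(img, AugmentConfig(rotation_step_degrees=360.0, shifts=((2, 1),)))
        assert len(out) == 2
        assert out[1][4, 5, 0] == 1.0 and out[1][3, 3, 0] == 0.0

    def test_outputs_stay_in_unit_interval(self, rng):
        outs = augment(rng.uniform(size=(9, 9, 3)), AugmentConfig(shifts=((1.5, -0.5),)))
        for o in outs:
            assert o.min() >= 0.0 and o.max() <= 1.0

    def test_non_square_input_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(rng.uniform(size=(4, 6, 3)), AugmentConfig())

    def test_indivisible_step_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(rotation_step_degrees=50.0)


class TestQualityFilter:
    def test_constant_image_dropped(self, rng):
        kept, dropped = quality_filter([np.full((8, 8, 3), 0.5)], tau=0.02)
        assert kept == [] and len(dropped) == 1

    def test_zero_threshold_keeps_everything(self, rng):
        imgs = [rng.uniform(size=(4, 4, 3)) for _ in range(3)]
        kept, dropped = quality_filter(imgs, tau=0.0)
        assert len(kept) == 3 and dropped == []

    def test_separates_textured_scenes_from_constant_frames(self):
        from aqua_ae.synth import SceneParams, make_dataset

        frames, _ = make_dataset(
            10, SceneParams(height=32, width=32, contrast_delta=0.3, seed=3)
        )
        imgs = list(frames) + [np.full((32, 32, 3), 0.4)] * 5
        kept, dropped = quality_filter(imgs, tau=0.02)
        assert len(kept) == 10 and len(dropped) == 5


class TestPipeline:
    def test_output_count_and_manifest_determinism(self, tmp_path):
        src = tmp_path / "src"
        params = SceneParams(height=24, width=20, n_fish=1, seed=9)
        for i in range(4):
            img, boxes = compose_scene(SceneParams(
                height=24, width=20, n_fish=1, seed=9 + i))
            save_scene(src, i, img, boxes, params)
        cfg = PipelineConfig(target=16, augment=AugmentConfig(rotation_step_degrees=90.0))
        m1 = preprocess_pipeline(src, tmp_path / "out1", cfg)
        m2 = preprocess_pipeline(src, tmp_path / "out2", cfg)
        assert len(m1) == 4 * 4  # none filtered, 4 rotations each
        assert m1 == m2
        from PIL import Image

        first = np.asarray(Image.open(tmp_path / "out1" / m1[0]["output"]))
        assert first.shape == (16, 16, 3)

    def test_empty_source_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            preprocess_pipeline(tmp_path / "empty", tmp_path / "out")
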