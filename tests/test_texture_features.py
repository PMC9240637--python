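import math

import numpy as np
import pytest

from canopy_yield import ROI, directional_aggregate, glcm, texture_stats, \
    texture_vector, to_gray

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(gray, levels, distance, angle, symmetric):
    """Independent oracle: explicit pair enumeration over every pixel."""
    q = gray.astype(int) * levels // 256
    dr, dc = (d * distance for d in OFFSETS[angle])
    h, w = q.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    P[q[r2, c2], q[r, c]] += 1
    total = P.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs")
    return P / total


class TestToGray:
    def test_white_pixel(self):
        img = np.full((2, 2, 3), 255, np.uint8)
        assert (to_gray(img) == 255).all()

    def test_red_pixel_luminance(self):
        img = np.zeros((1, 1, 3), np.uint8)
        img[..., 0] = 255
        assert to_gray(img)[0, 0] == 76  # round(0.299*255)

    def test_per_band_mode_returns_channels(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (4, 4, 3), dtype=np.uint8)
        bands = to_gray(img, mode="per_band")
        assert bands.shape == (3, 4, 4)
        for k in range(3):
            assert (bands[k] == img[..., k]).all()


class TestGLCM:
    def test_two_row_image_is_diagonal(self):
        gray = np.array([[0, 0], [255, 255]], np.uint8)
        m = glcm(gray, None, levels=2, distance=1, angle=0, symmetric=True)
        np.testing.assert_allclose(m.P, np.diag([0.5, 0.5]))

    def test_constant_image_single_cell(self):
        gray = np.full((5, 5), 100, np.uint8)
        m = glcm(gray, None, levels=8, angle=45)
        k = 100 * 8 // 256
        assert m.P[k, k] == 1.0 and m.P.sum() == 1.0

    def test_horizontal_mirror_transposes_0_degrees(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gray = rng.integers(0, 256, (5, 5), dtype=np.uint8)
            a = glcm(gray, None, levels=4, angle=0, symmetric=False)
            b = glcm(gray[:, ::-1], None, levels=4, angle=0, symmetric=False)
            np.testing.assert_allclose(a.P, b.P.T)

    def test_no_valid_pairs_raises(self):
        gray = np.zeros((4, 4), np.uint8)
        with pytest.raises(ValueError, match="45"):
            glcm(gray, ROI(box=(0, 0, 1, 1)), levels=2, angle=45)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_enumeration_oracle(self, angle, symmetric):
        rng = np.random.default_rng(11)
        for _ in range(25):
            gray = rng.integers(0, 256, (6, 6), dtype=np.uint8)
            got = glcm(gray, None, levels=4, angle=angle, symmetric=symmetric)
            want = brute_force_glcm(gray, 4, 1, angle, symmetric)
            np.testing.assert_allclose(got.P, want, atol=1e-15)

    def test_roi_restriction_counts_only_inside_pairs(self):
        gray = np.arange(16, dtype=np.uint8).reshape(4, 4) * 16
        roi = ROI(box=(0, 0, 2, 4))  # left two columns
        m = glcm(gray, roi, levels=4, angle=0, symmetric=False)
        want = brute_force_glcm(gray[:, :2], 4, 1, 0, False)
        np.testing.assert_allclose(m.P, want)


class TestTextureStats:
    def test_two_level_diagonal(self):
        asm, ent, con, cor = texture_stats(np.diag([0.5, 0.5]))
        assert (asm, ent, con, cor) == pytest.approx((0.5, 1.0, 0.0, 1.0))

    def test_single_cell_matrix(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        asm, ent, con, cor = texture_stats(P)
        assert (asm, ent, con) == pytest.approx((1.0, 0.0, 0.0))
        assert math.isnan(cor)

    def test_uniform_matrix_closed_form(self):
        P = np.full((4, 4), 1 / 16)
        asm, ent, con, cor = texture_stats(P)
        assert asm == pytest.approx(1 / 16)
        assert ent == pytest.approx(4.0)
        assert cor == pytest.approx(0.0, abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            texture_stats(np.ones((3, 3)))


class TestDirectionalAggregate:
    def agg(self, con_values):
        per_angle = {a: (0.5, 1.0, c, 0.0)
                     for a, c in zip((0, 45, 90, 135), con_values)}
        return directional_aggregate(per_angle)

    def test_equal_angles_have_zero_sd(self):
        out = self.agg((1, 1, 1, 1))
        assert out["CON_MEAN"] == 1.0 and out["CON_SD"] == 0.0

    def test_population_sd(self):
        out = self.agg((0, 0, 2, 2))
        assert out["CON_MEAN"] == 1.0 and out["CON_SD"] == 1.0

    def test_nan_propagates(self):
        out = self.agg((1, float("nan"), 1, 1))
        assert math.isnan(out["CON_MEAN"]) and math.isnan(out["CON_SD"])

    def test_rotation_by_90_preserves_directional_means(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            img = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
            a = texture_vector(img, None, levels=4)
            b = texture_vector(np.rot90(img).copy(), None, levels=4)
            for stat in ("ASM", "ENT", "CON"):
                assert a[f"{stat}_MEAN"] == pytest.approx(b[f"{stat}_MEAN"])
                assert a[f"{stat}_SD"] == pytest.approx(b[f"{stat}_SD"])


def test_asm_maximal_iff_quantized_roi_constant():
    rng = np.random.default_rng(8)
    const = np.full((5, 5), 7, np.uint8)
    m = glcm(const, None, levels=4, angle=0)
    assert texture_stats(m)[0] == 1.0
    varied = rng.integers(0, 256, (5, 5), dtype=np.uint8)
    varied[0, 0] = 0
    varied[0, 1] = 255  # force two bins
    m = glcm(varied, None, levels=4, angle=0)
    assert texture_stats(m)[0] < 1.0


def test_contrast_rises_with_pixel_noise():
    """Additive DN noise roughens the tile, so GLCM contrast grows."""
    from canopy_yield import SceneParams, simulate_plot_image

    cons = []
    for sd in (0.0, 8.0, 25.0):
        p = SceneParams(tile_size=96, noise_sd=sd, seed=2)
        tile, _ = simulate_plot_image(p, 3.0, np.random.default_rng(2))
        cons.append(texture_vector(tile, None)["CON_MEAN"])
    assert cons[0] < cons[1] < cons[2]
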