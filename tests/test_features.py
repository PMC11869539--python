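"""Radiomic features against brute-force oracles and analytic shapes."""

import math

import numpy as np
import pytest

from imlts.features import (
    GLCMConfig,
    compute_glcm,
    extract_features,
    glcm_contrast,
    glcm_correlation,
    glcm_entropy,
    glcm_homogeneity,
    histogram_features,
    quantize,
    shape_features,
)
from imlts.imgio import ImageVolume, SegmentationMask
from imlts.phantom import Nodule, PhantomSpec, generate_phantom

AXIAL_OFFSETS = ((0, 1), (1, 0))


def brute_force_glcm(image, levels, offsets, symmetric):
    """Independent oracle: enumerate every voxel pair with explicit loops."""
    q = quantize(np.asarray(image, float), levels)
    counts = np.zeros((levels, levels))
    offs = list(offsets) + ([tuple(-o for o in off) for off in offsets] if symmetric else [])
    h, w = q.shape
    for off in offs:
        for y in range(h):
            for x in range(w):
                y2, x2 = y + off[0], x + off[1]
                if 0 <= y2 < h and 0 <= x2 < w:
                    counts[q[y, x], q[y2, x2]] += 1
    return counts / counts.sum()


def brute_force_features(glcm):
    n = glcm.shape[0]
    contrast = sum(glcm[i, j] * (i - j) ** 2 for i in range(n) for j in range(n))
    hom = sum(glcm[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    ent = -sum(glcm[i, j] * math.log(glcm[i, j]) for i in range(n) for j in range(n) if glcm[i, j] > 0)
    mx = sum(i * glcm[i, j] for i in range(n) for j in range(n))
    my = sum(j * glcm[i, j] for i in range(n) for j in range(n))
    vx = sum((i - mx) ** 2 * glcm[i, j] for i in range(n) for j in range(n))
    vy = sum((j - my) ** 2 * glcm[i, j] for i in range(n) for j in range(n))
    corr = sum(
        glcm[i, j] * (i - mx) * (j - my) for i in range(n) for j in range(n)
    ) / math.sqrt(vx * vy)
    return contrast, corr, hom, ent


class TestGLCM:
    def test_constant_roi_is_single_diagonal_entry(self):
        g = compute_glcm(np.full((4, 4), 9.0), config=GLCMConfig(levels=4))
        assert g[0, 0] == pytest.approx(1.0)
        assert g.sum() == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        cfg = GLCMConfig(levels=2, offsets=((0, 1),), symmetric=False)
        g = compute_glcm(img, config=cfg)
        # exactly two rightward pairs, both 0 -> 1
        assert g[0, 1] == pytest.approx(1.0)

    def test_normalization_on_random_images(self, rng):
        for _ in range(5):
            g = compute_glcm(rng.normal(size=(8, 8)), config=GLCMConfig(levels=8))
            assert g.sum() == pytest.approx(1.0, abs=1e-12)
            assert (g >= 0).all()

    def test_mask_restricts_pairs(self):
        img = np.array([[0.0, 0.0, 9.0], [0.0, 0.0, 9.0]])
        mask = np.array([[1, 1, 0], [1, 1, 0]], bool)
        g = compute_glcm(img, mask, GLCMConfig(levels=2, offsets=((0, 1),)))
        assert g[0, 0] == pytest.approx(1.0)  # bright column never paired

    def test_all_four_features_match_oracle_on_random_images(self, rng):
        cfg = GLCMConfig(levels=8, offsets=AXIAL_OFFSETS, symmetric=True)
        for _ in range(20):
            img = rng.random((8, 8))
            g = compute_glcm(img, config=cfg)
            ref = brute_force_glcm(img, 8, AXIAL_OFFSETS, True)
            assert np.allclose(g, ref, atol=1e-12)
            c0, r0, h0, e0 = brute_force_features(ref)
            assert glcm_contrast(g) == pytest.approx(c0, abs=1e-12)
            assert glcm_correlation(g) == pytest.approx(r0, abs=1e-12)
            assert glcm_homogeneity(g) == pytest.approx(h0, abs=1e-12)
            assert glcm_entropy(g) == pytest.approx(e0, abs=1e-12)

    def test_checkerboard_closed_forms(self):
        cb = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        cfg = GLCMConfig(levels=2, offsets=AXIAL_OFFSETS, symmetric=True)
        g = compute_glcm(cb, config=cfg)
        assert glcm_contrast(g) == pytest.approx(1.0)
        assert glcm_homogeneity(g) == pytest.approx(0.5)
        assert glcm_correlation(g) == pytest.approx(-1.0)

    def test_monotone_gradient_is_positively_correlated(self):
        img = np.tile(np.arange(32.0), (8, 1))
        g = compute_glcm(img, config=GLCMConfig(levels=32, offsets=((0, 1),)))
        assert glcm_correlation(g) > 0.95

    def test_uniform_entropy_closed_form(self):
        g = np.full((2, 2), 0.25)
        assert glcm_entropy(g) == pytest.approx(math.log(4))

    def test_contrast_and_homogeneity_move_oppositely_with_frequency(self):
        # stripes of decreasing period: contrast rises, homogeneity falls
        cfg = GLCMConfig(levels=2, offsets=AXIAL_OFFSETS)
        contrasts, homogeneities = [], []
        for period in (8, 4, 2):
            img = ((np.indices((16, 16)).sum(axis=0) // period) % 2).astype(float)
            g = compute_glcm(img, config=cfg)
            contrasts.append(glcm_contrast(g))
            homogeneities.append(glcm_homogeneity(g))
        assert contrasts == sorted(contrasts)
        assert homogeneities == sorted(homogeneities, reverse=True)

    def test_degenerate_correlation_errors(self):
        g = np.zeros((4, 4))
        g[2, 2] = 1.0
        with pytest.raises(ValueError, match="variance"):
            glcm_correlation(g)


class TestShapeFeatures:
    def test_pixel_count_area_arithmetic(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[2, 1:6] = 1
        mask[3, 1:6] = 1  # 10 pixels
        area, *_ = shape_features(SegmentationMask(mask, (0.5, 0.5)))
        assert area == pytest.approx(2.5)

    def test_disk_is_round(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2).astype(np.uint8)
        area, aspect, roundness, perimeter, circ = shape_features(
            SegmentationMask(disk, (1.0, 1.0))
        )
        assert 0.9 <= roundness <= 1.1
        assert 0.9 <= circ <= 1.1
        assert 1.0 <= aspect <= 1.1
        assert perimeter == pytest.approx(2 * math.pi * 20, rel=0.05)

    def test_two_to_one_ellipse_aspect(self):
        yy, xx = np.mgrid[0:80, 0:80]
        ell = (((yy - 40) / 30.0) ** 2 + ((xx - 40) / 15.0) ** 2 <= 1).astype(np.uint8)
        _, aspect, *_ = shape_features(SegmentationMask(ell, (1.0, 1.0)))
        assert aspect == pytest.approx(2.0, rel=0.05)

    def test_3d_mask_uses_largest_axial_slice(self):
        mask = np.zeros((5, 32, 32), np.uint8)
        mask[2, 10:20, 10:20] = 1  # largest slice: 10x10 square
        mask[3, 12:14, 12:14] = 1
        area, *_ = shape_features(SegmentationMask(mask, (1.0, 0.5, 0.5)))
        assert area == pytest.approx(100 * 0.25)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            shape_features(SegmentationMask(np.zeros((8, 8), np.uint8), (1, 1)))


class TestHistogramFeatures:
    def test_delta_histogram(self):
        vals = np.full((4, 4), 3.3)
        uni, mean, var, kurt, skew, smooth = histogram_features(vals)
        assert (uni, var, skew, smooth) == (1.0, 0.0, 0.0, 0.0)
        assert mean == pytest.approx(3.3)

    def test_symmetric_two_point_histogram(self):
        vals = np.array([-1.0, 1.0, 1.0, -1.0])
        uni, mean, var, kurt, skew, smooth = histogram_features(vals)
        assert uni == pytest.approx(0.5)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert var == pytest.approx(1.0, rel=0.01)  # bin-centre quantization
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_uniform_histogram_uniformity(self):
        levels = 16
        vals = np.repeat(np.arange(levels, dtype=float), 4)
        uni, *_ = histogram_features(vals, levels=levels)
        assert uni == pytest.approx(1.0 / levels)

    def test_needs_two_voxels(self):
        with pytest.raises(ValueError, match=">= 2"):
            histogram_features(np.array([1.0]))


class TestExtractFeatures:
    @pytest.fixture
    def noisy_pair(self):
        spec = PhantomSpec(
            image_shape=(128, 128),
            spacing_mm=(0.5, 0.5),
            nodules=(Nodule((64.0, 64.0), 10.0),),
            noise_sigma=10.0,
            seed=4,
        )
        img, mask, _ = generate_phantom(spec)
        return img, mask

    def test_all_bounds_hold_on_phantom(self, noisy_pair):
        img, mask = noisy_pair
        fv = extract_features(img, mask)
        assert 0 < fv.homogeneity <= 1
        assert 0 < fv.uniformity <= 1
        assert fv.entropy >= 0
        assert fv.area_mm2 >= 0 and fv.perimeter_mm >= 0
        assert fv.aspect_rate >= 1

    def test_shape_features_noise_invariant_texture_not(self):
        def make(seed):
            spec = PhantomSpec(
                image_shape=(128, 128),
                spacing_mm=(0.5, 0.5),
                nodules=(Nodule((64.0, 64.0), 10.0),),
                noise_sigma=10.0,
                seed=seed,
            )
            return generate_phantom(spec)[:2]

        (img1, mask1), (img2, mask2) = make(1), make(2)
        f1 = extract_features(img1, mask1)
        f2 = extract_features(img2, mask2)
        for name in ("area_mm2", "aspect_rate", "roundness", "perimeter_mm", "circularity"):
            assert getattr(f1, name) == getattr(f2, name)
        assert f1.entropy != f2.entropy

    def test_translation_invariance_of_texture(self, rng):
        base = rng.normal(size=(32, 32))
        mask = np.zeros((32, 32), np.uint8)
        mask[8:18, 8:18] = 1
        img1 = ImageVolume(base, (1, 1))
        img2 = ImageVolume(np.roll(base, (5, 5), axis=(0, 1)), (1, 1))
        m2 = np.roll(mask, (5, 5), axis=(0, 1))
        f1 = extract_features(img1, SegmentationMask(mask, (1, 1)))
        f2 = extract_features(img2, SegmentationMask(m2, (1, 1)))
        for name in ("contrast", "correlation", "homogeneity", "entropy",
                     "uniformity", "mean", "standard_variance"):
            assert getattr(f1, name) == pytest.approx(getattr(f2, name), abs=1e-12)
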