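"""Patch extraction, GLCM oracle equivalence, Hu invariances, shape, 40-bank."""

import numpy as np
import pandas as pd
import pytest

from collateralis.features import (
    DEFAULT_OFFSETS,
    FEATURE_NAMES,
    GLCM_FEATURE_NAMES,
    MOMENT_FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    Patch,
    build_feature_table,
    extract_patches,
    glcm,
    glcm_features,
    hu_moments,
    shape_features,
)


class TestExtractPatches:
    def test_count_256_image_block16_shift1(self):
        patches = extract_patches(np.zeros((256, 256)), block=16, shift=1)
        assert len(patches) == 58081

    def test_block_equal_to_image_gives_one_patch(self, rng):
        img = rng.normal(size=(16, 16))
        patches = extract_patches(img, block=16, shift=1)
        assert len(patches) == 1
        assert np.array_equal(patches[0].data, img)

    def test_shift_two_offsets(self):
        patches = extract_patches(np.zeros((20, 20)), block=16, shift=2)
        assert len(patches) == 9
        assert sorted({p.row for p in patches}) == [0, 2, 4]
        assert sorted({p.col for p in patches}) == [0, 2, 4]

    def test_block_exceeding_image_rejected(self):
        with pytest.raises(ValueError, match="block"):
            extract_patches(np.zeros((10, 10)), block=16)


def _brute_force_glcm(patch, levels, offsets):
    """Independent double-loop pair counter."""
    arr = np.asarray(patch, dtype=float)
    lo, span = arr.min(), np.ptp(arr)
    if span == 0:
        q = np.zeros(arr.shape, dtype=int)
    else:
        q = np.minimum(((arr - lo) / span * levels).astype(int), levels - 1)
    counts = np.zeros((levels, levels))
    rows, cols = q.shape
    for r in range(rows):
        for c in range(cols):
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


class TestGlcm:
    def test_hand_enumerated_two_by_two(self):
        p = glcm(np.array([[0.0, 0.0], [1.0, 1.0]]), levels=2, offsets=((0, 1),))
        expected = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert np.array_equal(p, expected)

    def test_constant_patch_single_diagonal_cell(self):
        p = glcm(np.full((8, 8), 3.0), levels=8)
        assert p[0, 0] == 1.0
        assert p.sum() == 1.0

    def test_matches_brute_force_oracle_on_100_random_patches(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            patch = rng.uniform(0, 10, size=(8, 8))
            fast = glcm(patch, levels=8)
            slow = _brute_force_glcm(patch, 8, DEFAULT_OFFSETS)
            assert np.array_equal(fast, slow)

    def test_normalized_and_symmetric(self, rng):
        p = glcm(rng.normal(size=(16, 16)))
        assert p.sum() == pytest.approx(1.0)
        assert np.array_equal(p, p.T)


class TestGlcmFeatures:
    def test_diagonal_matrix_zero_contrast_dissimilarity(self):
        p = np.diag([0.25, 0.25, 0.25, 0.25])
        f = glcm_features(p)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_dissimilarity"] == 0.0

    def test_uniform_matrix_closed_forms(self):
        n = 4
        f = glcm_features(np.full((n, n), 1.0 / n**2))
        assert f["glcm_energy"] == pytest.approx(1.0 / n**2)
        assert f["glcm_entropy"] == pytest.approx(2 * np.log2(n))

    def test_two_by_two_hand_values(self):
        f = glcm_features(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_entropy"] == pytest.approx(1.0)
        assert f["glcm_contrast"] == 0.0

    def test_degenerate_marginal_gives_zero_correlation(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        assert glcm_features(p)["glcm_correlation"] == 0.0

    def test_feature_count_is_22(self, rng):
        f = glcm_features(glcm(rng.normal(size=(16, 16))))
        assert len(f) == 22
        assert tuple(f) == GLCM_FEATURE_NAMES


def _brute_force_hu(patch):
    """Independent double-summation implementation of the seven invariants."""
    a = np.asarray(patch, dtype=float)
    a = a / a.max()
    rows, cols = a.shape
    m = {}
    for p in range(4):
        for q in range(4):
            s = 0.0
            for y in range(rows):
                for x in range(cols):
                    s += (x**p) * (y**q) * a[y, x]
            m[(p, q)] = s
    xb, yb = m[(1, 0)] / m[(0, 0)], m[(0, 1)] / m[(0, 0)]
    eta = {}
    for p in range(4):
        for q in range(4):
            mu = 0.0
            for y in range(rows):
                for x in range(cols):
                    mu += ((x - xb) ** p) * ((y - yb) ** q) * a[y, x]
            eta[(p, q)] = mu / m[(0, 0)] ** (1 + (p + q) / 2.0)
    n20, n02, n11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    n30, n03, n21, n12 = eta[(3, 0)], eta[(0, 3)], eta[(2, 1)], eta[(1, 2)]
    return np.array([
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11**2,
        (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2,
        (n30 + n12) ** 2 + (n21 + n03) ** 2,
        (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
        (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (n30 + n12) * (n21 + n03),
        (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
    ])


@pytest.fixture
def asymmetric_patch(rng):
    patch = np.zeros((16, 16))
    patch[3:9, 4:7] = rng.uniform(0.5, 1.0, size=(6, 3))
    patch[10:13, 8:14] = rng.uniform(0.2, 0.6, size=(3, 6))
    return patch


class TestHuMoments:
    def test_translation_invariance(self):
        canvas = np.zeros((24, 24))
        canvas[4:8, 4:8] = np.arange(16).reshape(4, 4) + 1.0
        shifted = np.zeros((24, 24))
        shifted[7:11, 9:13] = np.arange(16).reshape(4, 4) + 1.0
        a, b = hu_moments(canvas), hu_moments(shifted)
        assert np.allclose(a, b, rtol=1e-8, atol=1e-14)

    def test_rotation_90_and_180_invariance(self, asymmetric_patch):
        a = hu_moments(asymmetric_patch)
        for k in (1, 2):
            b = hu_moments(np.rot90(asymmetric_patch, k))
            assert np.allclose(a, b, rtol=1e-9)

    def test_reflection_flips_phi7_only(self, asymmetric_patch):
        a = hu_moments(asymmetric_patch)
        b = hu_moments(np.fliplr(asymmetric_patch))
        assert np.allclose(a[:6], b[:6], rtol=1e-9)
        assert np.isclose(a[6], -b[6], rtol=1e-9)

    def test_intensity_scaling_invariance(self, asymmetric_patch):
        a = hu_moments(asymmetric_patch)
        b = hu_moments(asymmetric_patch * 37.5)
        assert np.allclose(a, b, rtol=1e-6)

    def test_matches_brute_force_double_summation(self):
        patch = np.zeros((16, 16))
        patch[6:10, 6:10] = 1.0
        assert np.allclose(hu_moments(patch), _brute_force_hu(patch), rtol=1e-12, atol=1e-300)

    def test_matches_skimage_cross_check(self, asymmetric_patch):
        from skimage.measure import moments_central, moments_hu, moments_normalized

        # skimage indexes moments row-first; transpose to match the x=col convention
        norm = (asymmetric_patch / asymmetric_patch.max()).T
        expected = moments_hu(moments_normalized(moments_central(norm)))
        assert np.allclose(hu_moments(asymmetric_patch), expected, rtol=1e-8)

    def test_all_zero_patch_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            hu_moments(np.zeros((8, 8)))


class TestShapeFeatures:
    def test_full_foreground_patch(self):
        f = shape_features(np.full((16, 16), 5.0))
        assert f["shape_area"] == 256.0
        assert f["shape_extent"] == 1.0

    def test_disc_rounder_than_bar(self):
        yy, xx = np.ogrid[:20, :20]
        disc = (np.hypot(yy - 10, xx - 10) <= 5).astype(float)
        bar = np.zeros((20, 20))
        bar[9:11, 1:19] = 1.0
        assert shape_features(disc)["shape_circularity"] > shape_features(bar)["shape_circularity"]

    def test_bar_aspect_ratio(self):
        bar = np.zeros((16, 16))
        bar[7:9, 3:13] = 1.0  # 2x10 bar
        assert shape_features(bar)["shape_aspect_ratio"] >= 4.0

    def test_feature_count_is_11(self, rng):
        f = shape_features(rng.normal(size=(16, 16)))
        assert tuple(f) == SHAPE_FEATURE_NAMES


class TestFeatureTable:
    def test_exactly_40_feature_columns(self, rng):
        patches = [Patch(rng.uniform(0, 1, size=(16, 16)), r, 0, label=r % 2) for r in range(4)]
        table = build_feature_table(patches)
        feature_cols = [c for c in table.columns if c not in ("label", "row", "col")]
        assert len(feature_cols) == 40
        assert feature_cols == list(FEATURE_NAMES)

    def test_moment_group_has_7_columns(self):
        assert len(MOMENT_FEATURE_NAMES) == 7

    def test_identical_patches_identical_rows(self, rng):
        block = rng.uniform(0, 1, size=(16, 16))
        table = build_feature_table([Patch(block, 0, 0, 0), Patch(block.copy(), 0, 0, 0)])
        assert table.iloc[0].equals(table.iloc[1])

    def test_order_independent(self, rng):
        patches = [Patch(rng.uniform(0, 1, size=(16, 16)), r, 0, label=r % 2) for r in range(6)]
        t1 = build_feature_table(patches)
        t2 = build_feature_table(patches[::-1])
        merged = t2.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, merged)

    def test_all_zero_patch_gets_zero_hu_block(self):
        table = build_feature_table([Patch(np.zeros((16, 16)), 0, 0, 1)])
        assert (table[list(MOMENT_FEATURE_NAMES)].iloc[0] == 0).all()

    def test_empty_patch_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_feature_table([])
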