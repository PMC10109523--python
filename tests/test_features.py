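import itertools

import numpy as np
import pytest

from tumorkit import features
from tumorkit.errors import ShapeError
from tumorkit.features import (FEATURE_BLOCKS, dwt_features, extract_all,
                               feature_names, glcm_features,
                               intensity_features, texture_features)
from tumorkit.image_io import GrayImage2D


def gray(arr, vr="byte"):
    return GrayImage2D(np.asarray(arr, dtype=float), value_range=vr)


def brute_force_glcm(img, dx=1, dy=0, levels=256):
    """Independent oracle: count horizontal neighbour pairs directly."""
    img = np.asarray(img, dtype=int)
    P = np.zeros((levels, levels))
    H, W = img.shape
    for i in range(H):
        for j in range(W):
            i2, j2 = i + dy, j + dx
            if 0 <= i2 < H and 0 <= j2 < W:
                P[img[i, j], img[i2, j2]] += 1
                P[img[i2, j2], img[i, j]] += 1  # symmetric
    P /= P.sum()
    idx = np.arange(levels)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = ((ii - jj) ** 2 * P).sum()
    dissim = (np.abs(ii - jj) * P).sum()
    homog = (P / (1.0 + (ii - jj) ** 2)).sum()
    asm = (P ** 2).sum()
    energy = np.sqrt(asm)
    px = P.sum(1)
    mu = (idx * px).sum()
    sd = np.sqrt(((idx - mu) ** 2 * px).sum())
    if sd == 0:
        corr = 1.0
    else:
        corr = ((ii - mu) * (jj - mu) * P).sum() / sd ** 2
    return np.array([contrast, dissim, homog, asm, energy, corr])


class TestIntensity:
    def test_constant_image_guard(self):
        np.testing.assert_array_equal(intensity_features(gray(np.full((6, 6), 5.0))),
                                      [5, 0, 0, 0])

    def test_symmetric_two_point_distribution(self):
        arr = np.concatenate([np.zeros(50), np.full(50, 255.0)]).reshape(10, 10)
        feats = intensity_features(gray(arr))
        assert feats[2] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_3x3(self):
        feats = intensity_features(gray(np.arange(9.0).reshape(3, 3)))
        assert feats[0] == pytest.approx(4.0)
        assert feats[1] == pytest.approx(60.0 / 9.0)

    def test_matches_direct_moments_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            arr = rng.integers(0, 256, (17, 23)).astype(float)
            mean, var, skew, kurt = intensity_features(gray(arr))
            assert mean == pytest.approx(arr.mean(), abs=1e-10)
            assert var == pytest.approx(arr.var(), abs=1e-10)
            z = (arr - arr.mean()) / arr.std()
            assert skew == pytest.approx((z ** 3).mean(), abs=1e-10)
            assert kurt == pytest.approx((z ** 4).mean() - 3, abs=1e-10)


class TestGLCM:
    def test_constant_image_limits(self):
        contrast, dissim, homog, asm, energy, corr = glcm_features(
            gray(np.full((5, 5), 7.0)))
        assert (contrast, dissim) == (0.0, 0.0)
        assert (homog, asm, energy) == (1.0, 1.0, 1.0)
        assert corr == 1.0

    def test_two_column_alternation(self):
        feats = glcm_features(gray(np.array([[0, 1], [0, 1]], dtype=float)))
        assert feats[0] == pytest.approx(1.0)  # contrast: both pairs differ by 1

    def test_exhaustive_2x2_four_levels(self):
        for vals in itertools.product(range(4), repeat=4):
            arr = np.array(vals, dtype=float).reshape(2, 2)
            got = glcm_features(gray(arr))
            np.testing.assert_allclose(got, brute_force_glcm(arr), atol=1e-10)

    def test_random_4x4_four_levels_vs_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            arr = rng.integers(0, 4, (4, 4)).astype(float)
            np.testing.assert_allclose(glcm_features(gray(arr)),
                                       brute_force_glcm(arr), atol=1e-10)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 256, (12, 12)).astype(float)
        np.testing.assert_allclose(glcm_features(gray(arr)),
                                   glcm_features(gray(arr[:, ::-1])), atol=1e-12)

    def test_single_column_raises(self):
        with pytest.raises(ShapeError):
            glcm_features(gray(np.zeros((5, 1))))


class TestDWT:
    def test_constant_image_has_no_detail(self):
        feats = dwt_features(gray(np.full((8, 8), 33.0)))
        # LH, HL, HH means and energies all zero
        np.testing.assert_allclose(feats[2:], 0.0, atol=1e-10)

    def test_2x2_constant_ll_coefficient(self):
        a = 37.0
        feats = dwt_features(gray(np.full((2, 2), a)))
        assert feats[0] == pytest.approx(2 * a)        # single LL coefficient
        assert feats[1] == pytest.approx((2 * a) ** 2)

    def test_vertical_step_energy_in_one_detail_band(self):
        # odd-column edge so the step falls inside Haar coefficient pairs
        arr = np.zeros((16, 16))
        arr[:, 9:] = 255.0
        feats = dwt_features(gray(arr))
        lh_energy, hl_energy, hh_energy = feats[3], feats[5], feats[7]
        detail = sorted([lh_energy, hl_energy])
        assert detail[1] > 0.0 and detail[0] == pytest.approx(0.0, abs=1e-10)
        assert hh_energy == pytest.approx(0.0, abs=1e-10)

    def test_odd_size_padding(self):
        feats = dwt_features(gray(np.random.default_rng(0).random((7, 9)) * 255))
        assert np.all(np.isfinite(feats)) and len(feats) == 8


class TestTextureBlock:
    def test_constant_image_zero_entropy(self):
        entropy, lbp, haralick = texture_features(gray(np.full((8, 8), 9.0)))
        assert entropy == 0.0
        assert np.all(np.isfinite(haralick))

    def test_fair_coin_entropy_one_bit(self):
        arr = np.zeros((8, 8))
        arr[:4] = 255.0
        entropy, _, _ = texture_features(gray(arr))
        assert entropy == pytest.approx(1.0)

    def test_lbp_histogram_normalized(self, tumor_phantom):
        img, _, _ = tumor_phantom
        _, lbp, _ = texture_features(img)
        assert len(lbp) == 10
        assert lbp.sum() == pytest.approx(1.0)

    def test_haralick_asm_matches_glcm_style_definition(self):
        # direction-averaged ASM of a constant image is 1
        _, _, haralick = texture_features(gray(np.full((6, 6), 3.0)))
        assert haralick[0] == pytest.approx(1.0)
        assert haralick[2] == pytest.approx(1.0)  # correlation guard


class TestExtractAll:
    def test_vector_length_and_block_order(self, tumor_phantom):
        img, _, _ = tumor_phantom
        fv = extract_all(img, name="Y1.png", label=1)
        assert len(fv) == 42
        assert fv.names == feature_names()
        assert len(fv.block("intensity")) == 4
        assert len(fv.block("glcm")) == 6
        assert len(fv.block("dwt")) == 8
        assert len(fv.block("other")) == 24
        assert FEATURE_BLOCKS["all"] == slice(0, 42)

    def test_deterministic(self, tumor_phantom):
        img, _, _ = tumor_phantom
        np.testing.assert_array_equal(extract_all(img).values,
                                      extract_all(img).values)

    def test_sensitive_to_single_pixel_change(self, tumor_phantom):
        img, _, _ = tumor_phantom
        other = GrayImage2D(img.pixels.copy(), value_range="byte")
        other.pixels[100, 100] = (other.pixels[100, 100] + 100) % 255
        assert not np.array_equal(extract_all(img).values,
                                  extract_all(other).values)

    def test_invariant_to_channel_replication(self, tumor_phantom):
        img, _, _ = tumor_phantom
        rep = np.repeat(img.pixels[:, :, None], 3, axis=-1)
        np.testing.assert_allclose(features.intensity_features(rep),
                                   features.intensity_features(img.pixels))

    def test_table_round_trip(self, tmp_path, tumor_phantom, healthy_phantom):
        vecs = [extract_all(tumor_phantom[0], name="Y1.png", label=1),
                extract_all(healthy_phantom[0], name="N1.png", label=0)]
        path = tmp_path / "features.csv"
        features.write_feature_table(vecs, path)
        back = features.read_feature_table(path)
        assert [v.label for v in back] == [1, 0]
        np.testing.assert_allclose(back[0].values, vecs[0].values, rtol=1e-12)
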