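import math
import warnings

import numpy as np
import pytest

from rectex.errors import EmptyMaskError, UndefinedFeatureError
from rectex.roi_io import QuantizedROI, quantize_roi
from rectex import texture
from rectex.texture import (
    ANGLES,
    FEATURE_NAMES,
    compute_glcm,
    compute_grlm,
    dwt_features,
    extract_case_features,
    glcm_features,
    grlm_features,
    histogram_features,
    slice_features,
)

import oracles
from conftest import make_roi


def q_from_levels(levels, ng):
    return QuantizedROI(levels=np.asarray(levels), ng=ng)


class TestHistogram:
    @pytest.mark.parametrize(
        "values, ske, kur",
        [
            ([1.0, 2.0, 3.0], 0.0, 1.5),
            ([1.0, 1.0, 3.0], (16 / 27) / (8 / 9) ** 1.5, None),
            ([-1.0, 1.0, -1.0, 1.0], 0.0, 1.0),
        ],
    )
    def test_moment_examples(self, values, ske, kur):
        roi = make_roi([values])
        s, k = histogram_features(roi)
        assert s == pytest.approx(ske, abs=1e-12)
        if kur is not None:
            assert k == pytest.approx(kur, abs=1e-12)

    def test_kurtosis_is_pearson_not_excess(self, rng):
        """A large normal sample has kurtosis near 3, not 0."""
        roi = make_roi(rng.normal(100, 10, (100, 100)))
        _, k = histogram_features(roi)
        assert 2.8 < k < 3.2

    def test_constant_roi_flagged(self):
        with pytest.raises(UndefinedFeatureError):
            histogram_features(make_roi(np.full((3, 3), 5.0)))


class TestGLCM:
    def test_checkerboard_row(self):
        q = q_from_levels([[1, 2, 1, 2]], ng=2)
        P = compute_glcm(q, 1, 0).P
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(P, expected)

    def test_constant_roi_single_entry(self):
        q = q_from_levels([[1, 1], [1, 1]], ng=2)
        P = compute_glcm(q, 1, 0).P
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_single_column_has_no_horizontal_pair(self):
        q = q_from_levels([[1], [2], [1]], ng=2)
        with pytest.raises(UndefinedFeatureError):
            compute_glcm(q, 1, 0)

    def test_checkerboard_diss_entr(self):
        q = q_from_levels([[1, 2, 1, 2]], ng=2)
        corr, diss, entr = texture.glcm_features_partial(q, angles=(0,))
        assert diss == pytest.approx(1.0, abs=1e-12)
        assert entr == pytest.approx(math.log(2), abs=1e-12)

    def test_two_block_row_correlation(self):
        q = q_from_levels([[1, 1, 2, 2]], ng=2)
        corr, _, _ = glcm_features(q, angles=(0,))
        assert corr == pytest.approx(1 / 3, abs=1e-12)

    def test_constant_roi_corr_undefined_diss_entr_zero(self):
        q = q_from_levels(np.ones((3, 3), dtype=int), ng=2)
        corr, diss, entr = texture.glcm_features_partial(q)
        assert math.isnan(corr)
        assert diss == 0.0 and entr == 0.0
        with pytest.raises(UndefinedFeatureError):
            glcm_features(q)

    def test_matrix_invariants(self, rng):
        """P symmetric, sums to 1; ENTR <= ln(Ng^2); DISS <= Ng-1."""
        for _ in range(20):
            ng = int(rng.integers(2, 8))
            levels = rng.integers(0, ng + 1, (7, 7))
            if not (levels > 0).any():
                continue
            q = q_from_levels(levels, ng)
            for theta in ANGLES:
                try:
                    P = compute_glcm(q, 1, theta).P
                except UndefinedFeatureError:
                    continue
                np.testing.assert_allclose(P, P.T, atol=1e-15)
                assert P.sum() == pytest.approx(1.0)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, diss, entr = texture.glcm_features_partial(q)
            except UndefinedFeatureError:
                continue
            assert entr <= math.log(ng * ng) + 1e-12
            assert diss <= ng - 1 + 1e-12


class TestGRLM:
    def test_row_run_decomposition(self):
        rlm = compute_grlm(q_from_levels([[1, 1, 1, 2]], ng=2), theta=0)
        assert rlm.R[0, 2] == 1 and rlm.R[1, 0] == 1 and rlm.n_runs == 2

    def test_constant_square_two_runs(self):
        rlm = compute_grlm(q_from_levels([[1, 1], [1, 1]], ng=2), theta=0)
        assert rlm.R[0, 1] == 2 and rlm.n_runs == 2

    def test_single_pixel_single_run(self):
        rlm = compute_grlm(q_from_levels([[1]], ng=2), theta=0)
        assert rlm.n_runs == 1 and rlm.R[0, 0] == 1

    def test_feature_examples(self):
        lre, gln, lglre = grlm_features(
            q_from_levels([[1, 1, 1, 2]], ng=2), angles=(0,)
        )
        assert (lre, gln, lglre) == pytest.approx((5.0, 1.0, 0.625))
        lre, gln, lglre = grlm_features(
            q_from_levels([[1, 1], [1, 1]], ng=2), angles=(0,)
        )
        assert (lre, gln, lglre) == pytest.approx((4.0, 2.0, 1.0))
        lre, gln, lglre = grlm_features(q_from_levels([[1]], ng=2))
        assert (lre, gln, lglre) == pytest.approx((1.0, 1.0, 1.0))

    def test_mask_breaks_runs(self):
        # level 0 (outside mask) must terminate a run
        rlm = compute_grlm(q_from_levels([[1, 0, 1]], ng=2), theta=0)
        assert rlm.R[0, 0] == 2 and rlm.n_runs == 2

    def test_pixel_count_conservation(self, rng):
        """sum_ij j*R(i,j) equals the number of in-mask pixels."""
        levels = rng.integers(0, 4, (9, 9))
        q = q_from_levels(levels, 3)
        j = np.arange(1, 10)
        for theta in ANGLES:
            R = compute_grlm(q, theta).R
            assert (R * j[None, :R.shape[1]]).sum() == (levels > 0).sum()


class TestBruteForceEquivalence:
    def test_glcm_and_grlm_match_enumeration(self, rng):
        """Vectorized matrices equal pixelwise enumeration on random
        small masked images, exactly."""
        for _ in range(60):
            h, w = rng.integers(1, 9, 2)
            ng = int(rng.integers(2, 6))
            levels = rng.integers(0, ng + 1, (h, w))
            if not (levels > 0).any():
                continue
            q = q_from_levels(levels, ng)
            for theta in ANGLES:
                R = compute_grlm(q, theta).R
                Rb = oracles.grlm_brute(levels, ng, theta)
                np.testing.assert_array_equal(R[:, :Rb.shape[1]], Rb)
                try:
                    P = compute_glcm(q, 1, theta).P
                except UndefinedFeatureError:
                    assert oracles.glcm_brute(levels, ng, 1, theta).sum() == 0
                    continue
                np.testing.assert_array_equal(
                    P, oracles.glcm_brute(levels, ng, 1, theta)
                )


class TestScaledLevels:
    def test_scaled_levels_rescale_diss_only(self, rng):
        from rectex.roi_io import quantize_roi

        q = quantize_roi(make_roi(rng.random((10, 10)) * 40), ng=8)
        corr, diss, entr = glcm_features(q)
        corr_s, diss_s, entr_s = glcm_features(q, scaled_levels=True)
        assert diss_s == pytest.approx(diss / 8, rel=1e-12)
        assert corr_s == pytest.approx(corr, rel=1e-12)
        assert entr_s == pytest.approx(entr, rel=1e-12)


class TestRotationConsistency:
    def test_four_angle_averages_invariant_to_rot90(self, rng):
        img = rng.random((12, 12)) * 50
        q1 = quantize_roi(make_roi(img), ng=8)
        q2 = quantize_roi(make_roi(np.rot90(img)), ng=8)
        f1 = glcm_features(q1) + grlm_features(q1)
        f2 = glcm_features(q2) + grlm_features(q2)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)


class TestDWT:
    def test_constant_image(self):
        c = 3.7
        hl, hh, hv, hd = dwt_features(make_roi(np.full((4, 4), c)))
        assert hl == pytest.approx(4 * c, abs=1e-9)
        assert (hh, hv, hd) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_two_row_bands(self):
        a, b = 5.0, 2.0
        img = np.array([[a] * 4, [a] * 4, [b] * 4, [b] * 4])
        hl, hh, hv, hd = dwt_features(make_roi(img))
        assert hl == pytest.approx(2 * (a + b), abs=1e-9)
        assert hh == pytest.approx(2 * abs(a - b), abs=1e-9)
        assert (hv, hd) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_transpose_swaps_h_and_v(self, rng):
        img = rng.random((8, 8)) * 10
        hl, hh, hv, hd = dwt_features(make_roi(img))
        tl, th, tv, td = dwt_features(make_roi(img.T))
        assert (tl, td) == pytest.approx((hl, hd), abs=1e-9)
        assert (th, tv) == pytest.approx((hv, hh), abs=1e-9)

    def test_matches_manual_haar_on_full_mask(self, rng):
        """Feature path equals an explicit pairwise Haar on an exact
        multiple-of-4 box."""
        img = rng.random((8, 12)) * 100
        got = dwt_features(make_roi(img))
        expected = oracles.dwt2_features_brute(img)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_energy_conservation(self, rng):
        import pywt

        img = rng.random((8, 8)) * 10
        coeffs = pywt.wavedec2(img, "haar", mode="periodization", level=2)
        energy = np.sum(coeffs[0] ** 2) + sum(
            np.sum(c ** 2) for lev in coeffs[1:] for c in lev
        )
        assert energy == pytest.approx(np.sum(img ** 2), rel=1e-9)

    def test_tiny_bounding_box_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 2:8] = True  # 2-row bounding box
        with pytest.raises(EmptyMaskError):
            dwt_features(make_roi(np.random.default_rng(0).random((10, 10)),
                                  mask))


class TestCaseExtraction:
    def test_twenty_four_labeled_features(self, rng):
        img = rng.random((32, 32)) * 100
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        sag = make_roi(img, mask, "sagittal_fs")
        tra = make_roi(rng.random((32, 32)) * 100, mask, "transverse")
        feats = extract_case_features(sag, tra, ng=16)
        assert len(feats) == 24
        assert sorted(feats) == sorted(
            f"{p}_{n}" for p in ("sag", "tra") for n in FEATURE_NAMES
        )
        assert all(np.isfinite(v) for v in feats.values())

    def test_identical_slices_give_equal_features(self, rng):
        img = rng.random((32, 32)) * 100
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True
        feats = extract_case_features(
            make_roi(img, mask, "sagittal_fs"),
            make_roi(img, mask, "transverse"),
            ng=16,
        )
        for name in FEATURE_NAMES:
            assert feats[f"sag_{name}"] == feats[f"tra_{name}"]

    def test_constant_roi_flags_undefined_features(self):
        img = np.full((16, 16), 9.0)
        roi = make_roi(img, sequence_type="sagittal_fs")
        feats = slice_features(roi, ng=8)
        assert math.isnan(feats["SKE"]) and math.isnan(feats["KUR"])
        assert math.isnan(feats["CORR"])
        assert feats["DISS"] == 0.0 and feats["ENTR"] == 0.0
        assert feats["GLN"] > 0 and feats["LGLRE"] == 1.0
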