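import numpy as np
import pandas as pd
import pytest

from rectex.errors import EmptyMaskError
from rectex.pipeline import covariate_report
from rectex.roi_io import SliceROI
from rectex.synthetic import (
    CohortConfig,
    dice,
    generate_case,
    generate_cohort,
    perturb_mask,
    sample_covariates,
)
from rectex.texture import slice_features


class TestGenerateCase:
    def test_deterministic_for_same_inputs(self):
        cfg = CohortConfig(n_low=5, n_high=5)
        a = generate_case(cfg, "T34", 3)
        b = generate_case(cfg, "T34", 3)
        np.testing.assert_array_equal(a.sag_image, b.sag_image)
        np.testing.assert_array_equal(a.tra_mask, b.tra_mask)

    def test_different_seeds_differ(self):
        cfg = CohortConfig(n_low=5, n_high=5)
        a = generate_case(cfg, "T34", 3)
        b = generate_case(cfg, "T34", 4)
        assert not np.array_equal(a.sag_image, b.sag_image)

    def test_degenerate_field_gives_constant_roi(self):
        cfg = CohortConfig(
            n_low=5, n_high=5,
            hetero_low=(2.0, 0.0),
            core_boost_low=0.0,
            psf_sigma=0.0,
        )
        case = generate_case(cfg, "T12", 1)
        roi_vals = case.sag_image[case.sag_mask]
        assert np.unique(roi_vals).size == 1

    def test_lesion_brighter_than_background(self):
        cfg = CohortConfig(n_low=5, n_high=5)
        case = generate_case(cfg, "T12", 2)
        assert case.tra_image[case.tra_mask].mean() > \
            case.tra_image[~case.tra_mask].mean()
        assert (case.tra_image >= 0).all()

    def test_high_group_has_larger_roi_variance(self):
        """With a larger field SD (structure held equal), T3/4 lesions
        carry more intra-ROI variance on average."""
        cfg = CohortConfig(
            n_low=5, n_high=5,
            hetero_low=(2.0, 5.0), hetero_high=(2.0, 10.0),
            core_boost_low=45.0, core_boost_high=45.0,
        )
        var = {g: [] for g in ("T12", "T34")}
        for g in var:
            for i in range(50):
                c = generate_case(cfg, g, i)
                var[g].append(c.sag_image[c.sag_mask].var())
        assert np.mean(var["T34"]) > np.mean(var["T12"])

    def test_oversized_roi_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(image_size=32, roi_radius_range=(8.0, 20.0))

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            generate_case(CohortConfig(n_low=2, n_high=2), "T5", 0)


class TestDisorderMonotonicity:
    def test_entropy_and_dissimilarity_increase_with_field_sd(self):
        """Group-mean GLCM ENTR and DISS rise across three field-SD
        levels (50 cases each, structure fixed)."""
        means = []
        for sd in (3.0, 6.0, 12.0):
            cfg = CohortConfig(n_low=5, n_high=5, hetero_low=(2.0, sd))
            diss, entr = [], []
            for i in range(50):
                c = generate_case(cfg, "T12", i)
                f = slice_features(
                    SliceROI(c.sag_image, c.sag_mask, "sagittal_fs")
                )
                diss.append(f["DISS"])
                entr.append(f["ENTR"])
            means.append((np.mean(diss), np.mean(entr)))
        assert means[0][0] < means[1][0] < means[2][0]
        assert means[0][1] < means[1][1] < means[2][1]


class TestPerturbMask:
    @staticmethod
    def _disk(radius, size=64):
        rr, cc = np.mgrid[0:size, 0:size]
        return np.hypot(rr - size / 2, cc - size / 2) <= radius

    def test_zero_jitter_identity(self):
        mask = self._disk(10)
        new, d = perturb_mask(mask, 0.0, seed=1)
        np.testing.assert_array_equal(new, mask)
        assert d == 1.0

    def test_unit_jitter_keeps_high_overlap(self):
        mask = self._disk(20)
        for seed in range(5):
            new, d = perturb_mask(mask, 1.0, seed=seed)
            assert d >= 0.8
            assert new.any()

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            perturb_mask(np.zeros((16, 16), dtype=bool), 1.0, seed=0)

    def test_boundary_displacement_bounded(self):
        from scipy import ndimage

        mask = self._disk(15)
        new, _ = perturb_mask(mask, 2.0, seed=7)
        changed = mask ^ new
        # every flipped pixel lies within `jitter` of the old boundary
        inside = ndimage.distance_transform_edt(mask)
        outside = ndimage.distance_transform_edt(~mask)
        signed = np.abs(np.where(mask, inside - 0.5, outside - 0.5))
        assert signed[changed].max() <= 2.0 + 1e-9


class TestCohortOnDisk:
    def test_manifest_counts_and_files(self, tmp_path):
        cfg = CohortConfig(n_low=5, n_high=5, seed=9)
        manifest = generate_cohort(cfg, tmp_path)
        assert len(manifest) == 10
        assert (manifest["group"] == "T12").sum() == 5
        for col in ("sag_image", "sag_mask", "tra_image", "tra_mask",
                    "sag_mask_r2", "tra_mask_r2"):
            for name in manifest[col]:
                assert (tmp_path / name).exists()

    def test_reread_shapes_consistent(self, tmp_path):
        import imageio.v3 as iio

        cfg = CohortConfig(n_low=3, n_high=3, seed=2)
        manifest = generate_cohort(cfg, tmp_path)
        for rec in manifest.itertuples():
            img = iio.imread(tmp_path / rec.sag_image)
            msk = iio.imread(tmp_path / rec.sag_mask)
            assert img.shape == msk.shape

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = CohortConfig(n_low=3, n_high=3, seed=5)
        generate_cohort(cfg, tmp_path / "a")
        generate_cohort(cfg, tmp_path / "b")
        for name in ("manifest.csv", "case_0001_sag.png",
                     "case_0004_tra_mask_r2.png"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_nifti_output(self, tmp_path):
        cfg = CohortConfig(n_low=2, n_high=2, seed=1)
        manifest = generate_cohort(cfg, tmp_path, fmt="nifti")
        assert manifest["sag_image"].iloc[0].endswith(".nii.gz")
        assert (tmp_path / manifest["sag_image"].iloc[0]).exists()


class TestCovariates:
    def test_no_group_effect_encoded(self):
        """On large null cohorts every covariate comparison should be
        non-significant in most seeded runs."""
        clean = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            rows = []
            for g, n in (("T12", 500), ("T34", 500)):
                for _ in range(n):
                    row = {"group": g}
                    row.update(sample_covariates(r))
                    rows.append(row)
            report = covariate_report(pd.DataFrame(rows))
            clean += (report["p_value"] > 0.05).all()
        assert clean >= 7

    def test_covariate_levels(self):
        r = np.random.default_rng(0)
        cov = sample_covariates(r)
        assert cov["sex"] in ("M", "F")
        assert 50 <= cov["age"] <= 92
        assert 1.0 <= cov["diameter_cm"] <= 8.0
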