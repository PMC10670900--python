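"""Phantom simulator: determinism, anatomy coverage, degradation physics."""

import numpy as np
import pytest

from cbctsynth import (
    ArtifactSpec,
    BinaryMask,
    PhantomSpec,
    degrade_to_cbct,
    generate_dataset,
    generate_phantom_ct,
    mae_metric,
    ssim_metric,
)


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self, small_spec):
        a = generate_phantom_ct(small_spec, seed=5)
        b = generate_phantom_ct(small_spec, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self, small_spec):
        a = generate_phantom_ct(small_spec, seed=1)
        b = generate_phantom_ct(small_spec, seed=2)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_background_is_air(self, phantom_slice):
        body = phantom_slice.pixels > -1000.0
        # outside the body everything is exactly air
        assert np.all(phantom_slice.pixels[~body] == -1000.0)
        assert body.any()

    def test_zero_inserts_gives_soft_tissue_only(self):
        spec = PhantomSpec(
            image_size=64, bone_count_range=(0, 0), organ_count_range=(0, 0),
            texture_sigma=0.0,
        )
        img = generate_phantom_ct(spec, seed=3)
        assert not (img.pixels > 500.0).any()
        outside = img.pixels == -1000.0
        assert outside.any() and (~outside).any()

    def test_bone_region_populated_but_minority(self, small_spec):
        """Both sides of the 500 HU loss threshold must be populated."""
        for seed in range(10):
            img = generate_phantom_ct(small_spec, seed=seed)
            body = img.pixels > -500.0
            bone_frac = (img.pixels > 500.0).sum() / body.sum()
            assert 0.0 < bone_frac < 0.20

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_size=16)


class TestDegradeToCBCT:
    def test_identity_spec_is_identity(self, phantom_slice):
        out = degrade_to_cbct(phantom_slice, ArtifactSpec())
        assert np.array_equal(out.pixels, phantom_slice.pixels)
        assert out.modality == "CBCT"

    def test_shape_and_background_preserved(self, clinical_pair):
        cbct, pct = clinical_pair
        assert cbct.shape == pct.shape
        outside = pct.pixels == -1000.0
        assert np.all(cbct.pixels[outside] == -1000.0)

    def test_deterministic_in_artifact_seed(self, phantom_slice):
        a = degrade_to_cbct(phantom_slice, ArtifactSpec.clinical(seed=3))
        b = degrade_to_cbct(phantom_slice, ArtifactSpec.clinical(seed=3))
        c = degrade_to_cbct(phantom_slice, ArtifactSpec.clinical(seed=4))
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_mask_shape_mismatch_rejected(self, phantom_slice):
        bad = BinaryMask(np.ones((8, 8)))
        with pytest.raises(ValueError):
            degrade_to_cbct(phantom_slice, ArtifactSpec.clinical(), body_mask=bad)

    def test_noise_only_matches_folded_normal_mean(self, small_spec):
        """Additive N(0, s^2) noise gives body MAE of s*sqrt(2/pi)."""
        sigma = 30.0
        expected = sigma * np.sqrt(2.0 / np.pi)
        vals = []
        for seed in range(20):
            ct = generate_phantom_ct(small_spec, seed=seed)
            cb = degrade_to_cbct(ct, ArtifactSpec(noise_sigma=sigma, seed=seed))
            body = BinaryMask(ct.pixels > -500.0)
            vals.append(mae_metric(ct, cb, mask=body))
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_clinical_gap_brackets_clinical_scale(self, small_spec):
        """Mean CBCT-vs-CT MAE over seeded phantoms sits in the target band
        around the tens-of-HU gap typical of clinical cone-beam CT."""
        maes = [
            mae_metric(
                ct := generate_phantom_ct(small_spec, seed=s),
                degrade_to_cbct(ct, ArtifactSpec.clinical(seed=s)),
            )
            for s in range(50)
        ]
        assert 25.0 <= np.mean(maes) <= 120.0

    def test_noise_monotonicity_in_expectation(self, small_spec):
        means = []
        for sigma in (10.0, 30.0, 60.0):
            vals = []
            for seed in range(20):
                ct = generate_phantom_ct(small_spec, seed=seed)
                cb = degrade_to_cbct(ct, ArtifactSpec(noise_sigma=sigma, seed=seed))
                vals.append(mae_metric(ct, cb))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_invalid_contrast_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSpec(contrast_factor=0.0)
        with pytest.raises(ValueError):
            ArtifactSpec(noise_sigma=-1.0)


class TestGenerateDataset:
    def test_counts_and_patient_ids(self, tiny_dataset):
        assert len(tiny_dataset) == 10
        assert len(tiny_dataset.patient_ids()) == 5

    def test_deterministic(self, small_spec, tiny_dataset):
        again = generate_dataset(
            5, 2, spec=small_spec, artifact=ArtifactSpec.clinical(), seed=11
        )
        assert again.content_hash() == tiny_dataset.content_hash()

    def test_pairs_are_aligned_no_geometry_change(self, tiny_dataset):
        for s in tiny_dataset:
            assert s.cbct.shape == s.pct.shape
            # degradation does not move the body: air masks agree
            assert np.array_equal(
                s.cbct.pixels == -1000.0, s.pct.pixels == -1000.0
            )

    def test_dataset_ssim_leaves_enhancement_headroom(self, tiny_dataset):
        vals = [ssim_metric(s.pct, s.cbct) for s in tiny_dataset]
        assert np.mean(vals) < 0.95

    def test_fewer_than_three_patients_rejected(self, small_spec):
        with pytest.raises(ValueError):
            generate_dataset(2, 2, spec=small_spec, seed=0)

    def test_metal_insert_only_in_pct(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, metal_insert=True)
        ds = generate_dataset(3, 1, spec=spec, artifact=ArtifactSpec.clinical(), seed=2)
        for s in ds:
            assert (s.pct.pixels > 1500.0).any()
            assert not (s.cbct.pixels > 1500.0).any()

    @pytest.mark.parametrize("fmt,tol", [("tiff", 0.5), ("nifti", 1e-3)])
    def test_save_load_round_trip(self, tiny_dataset, tmp_path, fmt, tol):
        manifest = tiny_dataset.save(tmp_path / f"ds_{fmt}", fmt=fmt)
        loaded = type(tiny_dataset).load(manifest)
        assert len(loaded) == len(tiny_dataset)
        s0, l0 = tiny_dataset[0], loaded[0]
        assert l0.patient_id == s0.patient_id
        # TIFF stores rounded HU + offset; NIfTI stores float32 HU
        assert np.max(np.abs(l0.pct.pixels - s0.pct.pixels)) <= tol
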