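"""Body masking, foreign pixels, geometry, and the resolution pyramid."""

import numpy as np
import pytest

from cbctsynth import (
    ArtifactSpec,
    BinaryMask,
    HUImage,
    PhantomSpec,
    apply_mask,
    build_resolution_pyramid,
    center_crop,
    compute_body_mask,
    generate_dataset,
    generate_phantom_ct,
    replace_foreign_pixels,
    resize,
)
from cbctsynth.preprocess import downsample2, smooth_cycle, upsample2


def high_freq_energy(pixels):
    """Mean squared Laplacian: crude high-frequency content measure."""
    from scipy.ndimage import laplace

    return float((laplace(pixels) ** 2).mean())


class TestBodyMask:
    def test_recovers_phantom_body_within_boundary_band(self, phantom_slice):
        from scipy.ndimage import binary_dilation, binary_erosion

        mask = compute_body_mask(phantom_slice)
        true_body = phantom_slice.pixels > -1000.0
        band = 2
        inner = binary_erosion(true_body, iterations=band)
        outer = binary_dilation(true_body, iterations=band)
        assert np.all(mask.pixels[inner])  # everything well inside is kept
        assert not mask.pixels[~outer].any()  # nothing beyond a 2-px band

    def test_all_air_slice_raises_naming_threshold(self):
        img = HUImage(np.full((32, 32), -1000.0))
        with pytest.raises(ValueError, match="-300"):
            compute_body_mask(img)

    def test_largest_component_kept(self):
        pix = np.full((64, 64), -1000.0)
        pix[8:40, 8:40] = 40.0      # body
        pix[50:53, 50:53] = 40.0    # small satellite (couch debris)
        mask = compute_body_mask(HUImage(pix), morph_radius=1)
        assert mask.pixels[20, 20]
        assert not mask.pixels[51, 51]

    def test_masking_is_idempotent(self, phantom_slice):
        mask = compute_body_mask(phantom_slice)
        once = apply_mask(phantom_slice, mask)
        twice = apply_mask(once, compute_body_mask(once))
        assert np.array_equal(once.pixels, twice.pixels)


class TestApplyMask:
    def test_full_mask_identity(self, phantom_slice):
        full = BinaryMask(np.ones(phantom_slice.shape, dtype=bool))
        assert np.array_equal(
            apply_mask(phantom_slice, full).pixels, phantom_slice.pixels
        )

    def test_empty_mask_constant_fill(self, phantom_slice):
        empty = BinaryMask(np.zeros(phantom_slice.shape, dtype=bool))
        out = apply_mask(phantom_slice, empty, fill=-1000.0)
        assert np.all(out.pixels == -1000.0)

    def test_couch_bar_removed_body_untouched(self, phantom_slice):
        pix = phantom_slice.pixels.copy()
        pix[-3:, :] = 200.0  # couch-like bar outside the body
        with_couch = HUImage(pix)
        mask = compute_body_mask(phantom_slice)
        cleaned = apply_mask(with_couch, mask)
        assert np.all(cleaned.pixels[-1, :] == -1000.0)
        assert np.array_equal(
            cleaned.pixels[mask.pixels], phantom_slice.pixels[mask.pixels]
        )

    def test_shape_mismatch_rejected(self, phantom_slice):
        with pytest.raises(ValueError):
            apply_mask(phantom_slice, BinaryMask(np.ones((8, 8))))


class TestReplaceForeignPixels:
    def test_no_pixel_above_threshold_identity(self, clinical_pair):
        cbct, pct = clinical_pair
        out = replace_foreign_pixels(pct, cbct, threshold=1400.0)
        assert np.array_equal(out.pixels, pct.pixels)

    def test_exactly_the_metal_pixels_change(self, phantom_slice):
        pct_pix = phantom_slice.pixels.copy()
        coords = [(30, 30), (30, 31), (31, 30)]
        for c in coords:
            pct_pix[c] = 1500.0
        cbct_pix = phantom_slice.pixels.copy()
        for c in coords:
            cbct_pix[c] = 40.0
        out = replace_foreign_pixels(
            HUImage(pct_pix), HUImage(cbct_pix), threshold=1400.0
        )
        changed = out.pixels != pct_pix
        assert changed.sum() == 3
        assert all(out.pixels[c] == 40.0 for c in coords)

    def test_infinite_threshold_identity(self, clinical_pair):
        cbct, pct = clinical_pair
        out = replace_foreign_pixels(pct, cbct, threshold=np.inf)
        assert np.array_equal(out.pixels, pct.pixels)


class TestGeometry:
    def test_resize_identity(self, phantom_slice):
        assert resize(phantom_slice, 64) is phantom_slice

    def test_resize_checkerboard_block_replication(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 100.0
        up = resize(HUImage(board), 8)
        assert np.array_equal(up.pixels, np.kron(board, np.ones((2, 2))))
        assert up.spacing == pytest.approx(0.5)

    def test_varian_harmonisation_path(self):
        """512 -> 410 nearest-neighbour resize, then 400 center crop."""
        img = HUImage(np.random.default_rng(0).normal(0, 100, (512, 512)))
        out = center_crop(resize(img, 410), 400)
        assert out.shape == (400, 400)

    def test_center_crop_convention(self):
        img = HUImage(np.arange(36, dtype=float).reshape(6, 6))
        out = center_crop(img, 4)
        assert np.array_equal(out.pixels, img.pixels[1:5, 1:5])

    def test_center_crop_upsize_rejected(self, phantom_slice):
        with pytest.raises(ValueError):
            center_crop(phantom_slice, 128)


@pytest.fixture(scope="module")
def pyramid():
    ds = generate_dataset(
        3, 2, spec=PhantomSpec(image_size=64),
        artifact=ArtifactSpec.clinical(), seed=4,
    )
    return ds, build_resolution_pyramid(ds, n_levels=3)


class TestResolutionPyramid:

    def test_native_level_bit_identical(self, pyramid):
        ds, pyr = pyramid
        for orig, native in zip(ds, pyr[2]):
            assert np.array_equal(orig.pct.pixels, native.pct.pixels)
            assert np.array_equal(orig.cbct.pixels, native.cbct.pixels)

    def test_all_levels_native_dimensions(self, pyramid):
        _, pyr = pyramid
        for level in pyr.levels:
            for s in level:
                assert s.pct.shape == (64, 64)

    def test_constant_image_invariant(self):
        const = np.full((32, 32), 123.0)
        assert np.allclose(smooth_cycle(const, 2), const)

    def test_high_frequency_energy_nonincreasing(self, pyramid):
        _, pyr = pyramid
        for idx in range(len(pyr.levels[0])):
            energies = [
                high_freq_energy(pyr[k][idx].pct.pixels) for k in range(3)
            ]
            assert energies[0] <= energies[1] + 1e-9
            assert energies[1] <= energies[2] + 1e-9

    def test_checkerboard_smoothing_strict(self):
        board = (np.indices((64, 64)).sum(axis=0) % 2).astype(float) * 100.0
        assert high_freq_energy(smooth_cycle(board, 2)) < high_freq_energy(board)

    def test_divisibility_enforced(self):
        ds = generate_dataset(
            3, 1, spec=PhantomSpec(image_size=50),
            artifact=ArtifactSpec(), seed=0,
        )
        with pytest.raises(ValueError):
            build_resolution_pyramid(ds, n_levels=3)

    def test_downsample_then_upsample_shapes(self):
        x = np.random.default_rng(0).random((16, 16))
        assert downsample2(x).shape == (8, 8)
        assert upsample2(downsample2(x)).shape == (16, 16)


class TestOrderInvariance:
    def test_clip_and_mask_commute_with_air_fill(self, phantom_slice):
        from cbctsynth import clip_hu

        mask = compute_body_mask(phantom_slice)
        noisy = HUImage(phantom_slice.pixels + np.random.default_rng(1).normal(0, 400, phantom_slice.shape))
        a = clip_hu(apply_mask(noisy, mask, fill=-1000.0))
        b = apply_mask(clip_hu(noisy), mask, fill=-1000.0)
        assert np.array_equal(a.pixels, b.pixels)
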