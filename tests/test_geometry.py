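"""Projection geometry: adjointness, analytic oracles, FBP fidelity, masks."""

import numpy as np
import pytest

from limitedct import (ImageSlice, Sinogram, ViewMask, apply_view_mask,
                       back_project, fbp_reconstruct, fov_mask, insert_views,
                       psnr, radon_forward, uniform_angles)

from conftest import antialiased_disk


class TestRadonForward:
    def test_zero_image_gives_zero_sinogram(self):
        sino = radon_forward(ImageSlice(np.zeros((32, 32))),
                             uniform_angles(45))
        assert np.all(sino.values == 0.0)

    def test_rejects_non_square_and_non_finite(self):
        with pytest.raises(ValueError):
            radon_forward(ImageSlice(np.zeros((16, 32))), uniform_angles(10))
        bad = np.zeros((16, 16))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            radon_forward(bad, uniform_angles(10))

    def test_disk_projections_match_chord_lengths(self, disk64,
                                                  disk_sinogram):
        """Every view of a centered disk is the analytic chord-length
        profile 2*sqrt(r^2 - s^2)*density, up to discretization error."""
        r, density = 20.0, 0.8
        s = np.arange(64) - (64 - 1) / 2.0
        chord = 2.0 * np.sqrt(np.maximum(r * r - s * s, 0.0)) * density
        expected = np.broadcast_to(chord, disk_sinogram.values.shape)
        rel_l2 = (np.linalg.norm(disk_sinogram.values - expected)
                  / np.linalg.norm(expected))
        assert rel_l2 <= 0.02

    def test_disk_views_are_rotationally_symmetric(self, disk_sinogram):
        mean_row = disk_sinogram.values.mean(axis=0)
        dev = (np.linalg.norm(disk_sinogram.values - mean_row, axis=1)
               / np.linalg.norm(mean_row))
        # pixel-driven splatting aliases worst near 45 degrees
        assert dev.max() <= 0.10
        assert np.median(dev) <= 0.02

    def test_mass_preserved_per_view(self, phantom64, phantom_sinogram):
        """Sum over bins of each view equals the pixel sum (oracle:
        brute-force pixel sum), for an object inside the field of view."""
        mass = phantom64.sum()
        view_sums = phantom_sinogram.values.sum(axis=1)
        assert np.all(np.abs(view_sums - mass) / mass <= 0.01)

    def test_linearity(self, rng):
        x = rng.random((32, 32))
        y = rng.random((32, 32))
        angles = uniform_angles(30)
        lhs = radon_forward(ImageSlice(2.5 * x - 1.25 * y), angles).values
        rhs = (2.5 * radon_forward(ImageSlice(x), angles).values
               - 1.25 * radon_forward(ImageSlice(y), angles).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestAdjointness:
    def test_forward_and_backprojection_are_adjoint(self, rng):
        """<R x, y> == <x, B y> for 20 random 64x64 images and matching
        sinograms (oracle: direct inner products)."""
        angles = uniform_angles(50)
        for _ in range(20):
            x = rng.normal(size=(64, 64))
            y = rng.normal(size=(50, 64))
            rx = radon_forward(ImageSlice(x), angles).values
            by = back_project(Sinogram(y, angles), 64).pixels
            lhs = float((rx * y).sum())
            rhs = float((x * by).sum())
            assert abs(lhs - rhs) <= 1e-3 * abs(lhs)


class TestFBP:
    def test_zero_round_trip(self):
        sino = radon_forward(ImageSlice(np.zeros((32, 32))),
                             uniform_angles(60))
        rec = fbp_reconstruct(sino, 32)
        np.testing.assert_allclose(rec.pixels, 0.0, atol=1e-12)

    def test_empty_angle_set_rejected(self):
        sino = Sinogram(np.zeros((0, 32)), np.zeros(0))
        with pytest.raises(ValueError):
            fbp_reconstruct(sino, 32)

    def test_disk_recovered_within_10_percent(self, disk64, disk_sinogram):
        rec = fbp_reconstruct(disk_sinogram, 64)
        m = fov_mask(64)
        rel_rmse = (np.sqrt(np.mean((rec.pixels[m] - disk64[m]) ** 2))
                    / np.sqrt(np.mean(disk64[m] ** 2)))
        assert rel_rmse <= 0.10

    @pytest.mark.parametrize("size", [64, 128])
    def test_full_view_fbp_reaches_25db_in_fov(self, size):
        img = antialiased_disk(size, 0.3 * size, value=0.7)
        img += antialiased_disk(size, 0.12 * size, value=0.25)
        sino = radon_forward(ImageSlice(img), uniform_angles(180))
        rec = fbp_reconstruct(sino, size)
        m = fov_mask(size)
        mse = float(np.mean((rec.pixels[m] - img[m]) ** 2))
        assert 10 * np.log10(1.0 / mse) >= 25.0

    def test_limited_view_fbp_is_worse_than_full_view(self, phantom64,
                                                      phantom_sinogram,
                                                      cut_post_60):
        full_rec = fbp_reconstruct(phantom_sinogram, 64)
        lim = apply_view_mask(phantom_sinogram, cut_post_60)
        lim_rec = fbp_reconstruct(lim, 64)
        p_full = psnr(np.clip(full_rec.pixels, 0, 1), phantom64)
        p_lim = psnr(np.clip(lim_rec.pixels, 0, 1), phantom64)
        assert p_lim < p_full

    def test_agrees_with_independent_fbp_implementation(self, disk64,
                                                        disk_sinogram):
        """Cross-check against scikit-image's radon/iradon pair on the same
        phantom (different discretization, same reconstruction)."""
        from skimage.transform import iradon, radon as sk_radon

        mine = fbp_reconstruct(disk_sinogram, 64).pixels
        theirs = iradon(sk_radon(disk64, theta=uniform_angles(180)),
                        theta=uniform_angles(180), filter_name="ramp",
                        circle=True)
        m = fov_mask(64)
        rel = (np.linalg.norm((mine - theirs)[m])
               / np.linalg.norm(theirs[m]))
        assert rel <= 0.05

    @pytest.mark.parametrize("filter_name", ["shepp-logan", "hann"])
    def test_alternative_filters_also_reconstruct(self, disk64,
                                                  disk_sinogram, filter_name):
        rec = fbp_reconstruct(disk_sinogram, 64, filter_name=filter_name)
        m = fov_mask(64)
        rel_rmse = (np.sqrt(np.mean((rec.pixels[m] - disk64[m]) ** 2))
                    / np.sqrt(np.mean(disk64[m] ** 2)))
        assert rel_rmse <= 0.15


class TestViewMask:
    def test_no_missing_views_is_identity(self, phantom_sinogram):
        mask = ViewMask("cut_post", 0)
        out = apply_view_mask(phantom_sinogram, mask)
        np.testing.assert_array_equal(out.values, phantom_sinogram.values)

    def test_cut_post_60_keeps_first_120_views(self, phantom_sinogram):
        mask = ViewMask("cut_post", 60)
        out = apply_view_mask(phantom_sinogram, mask)
        assert out.n_views == 120
        np.testing.assert_array_equal(mask.measured_indices, np.arange(120))
        np.testing.assert_array_equal(out.values,
                                      phantom_sinogram.values[:120])

    @pytest.mark.parametrize("n_missing,n_kept", [(60, 120), (90, 90),
                                                  (120, 60)])
    def test_cut_mid_removes_centered_block(self, n_missing, n_kept):
        mask = ViewMask("cut_mid", n_missing)
        assert len(mask.measured_indices) == n_kept
        missing = mask.missing_indices
        # one contiguous centered block
        assert np.all(np.diff(missing) == 1)
        assert missing[0] == 90 - n_missing // 2
        # retained views split into two contiguous blocks
        gaps = np.sum(np.diff(mask.measured_indices) > 1)
        assert gaps == 1

    def test_rows_bit_identical(self, phantom_sinogram, cut_post_60):
        out = apply_view_mask(phantom_sinogram, cut_post_60)
        assert np.array_equal(
            out.values, phantom_sinogram.values[cut_post_60.measured_indices])

    def test_mask_round_trip(self, phantom_sinogram, cut_post_60):
        """Re-inserting limited rows into a zero full grid and masking again
        returns the limited sinogram exactly."""
        lim = apply_view_mask(phantom_sinogram, cut_post_60)
        grid = insert_views(lim, cut_post_60, phantom_sinogram.angles,
                            fill=0.0)
        again = apply_view_mask(grid, cut_post_60)
        assert np.array_equal(again.values, lim.values)

    def test_inconsistent_mask_rejected(self, phantom_sinogram):
        with pytest.raises(ValueError):
            apply_view_mask(phantom_sinogram, ViewMask("cut_post", 10,
                                                       n_full=90))


class TestFileIO:
    def test_sinogram_npz_round_trip(self, tmp_path, phantom_sinogram,
                                     cut_post_60):
        from limitedct import load_sinogram, save_sinogram

        lim = apply_view_mask(phantom_sinogram, cut_post_60)
        path = tmp_path / "sino.npz"
        save_sinogram(path, lim, cut_post_60)
        back, mask = load_sinogram(path)
        assert np.array_equal(back.values, lim.values)
        assert np.array_equal(back.angles, lim.angles)
        assert back.role == "limited"
        assert mask.scheme == "cut_post" and mask.n_missing == 60

    def test_tiff_round_trip_16bit(self, tmp_path, phantom64):
        from limitedct.geometry import load_slice_tiff, save_slice_tiff

        path = tmp_path / "slice.tiff"
        save_slice_tiff(path, ImageSlice(phantom64))
        back = load_slice_tiff(path)
        assert np.abs(back.pixels - phantom64).max() <= 1.0 / 65535.0


class TestSinogramValidation:
    def test_angles_must_match_rows(self):
        with pytest.raises(ValueError):
            Sinogram(np.zeros((10, 8)), np.arange(9))

    def test_angles_must_increase(self):
        with pytest.raises(ValueError):
            Sinogram(np.zeros((3, 8)), np.array([0.0, 2.0, 1.0]))

    def test_non_finite_rejected(self):
        v = np.zeros((3, 8))
        v[1, 2] = np.inf
        with pytest.raises(ValueError):
            Sinogram(v, np.arange(3.0))
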