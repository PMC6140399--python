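"""Phase correlation, sub-pixel refinement, Fourier shifting, grid solving."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mosaictomo import (
    MosaicGrid,
    ShiftTable,
    TileIndex,
    apply_fourier_shift,
    phase_correlate,
    register_grid,
    solve_positions,
    subpixel_refine,
)


@pytest.fixture(scope="module")
def smooth_image():
    """Strictly band-limited test image (all energy below 0.4 x Nyquist)."""
    rng = np.random.default_rng(7)
    img = gaussian_filter(rng.normal(size=(96, 96)), 2.0)
    spec = np.fft.fft2(img)
    fy = np.abs(np.fft.fftfreq(96))[:, None]
    fx = np.abs(np.fft.fftfreq(96))[None, :]
    spec[(fy > 0.2) | (fx > 0.2)] = 0.0
    img = np.fft.ifft2(spec).real
    return img / np.abs(img).max()


class TestApplyFourierShift:
    def test_zero_shift_identity(self, smooth_image):
        assert np.allclose(apply_fourier_shift(smooth_image, (0, 0)),
                           smooth_image, atol=1e-12)

    @pytest.mark.parametrize("shift", [(3, 0), (0, -5), (2, 7)])
    def test_integer_shift_equals_roll(self, smooth_image, shift):
        out = apply_fourier_shift(smooth_image, shift)
        assert np.allclose(out, np.roll(smooth_image, shift, axis=(0, 1)), atol=1e-9)

    def test_half_pixel_inverse_composition(self, smooth_image):
        out = apply_fourier_shift(apply_fourier_shift(smooth_image, (0.5, 0)),
                                  (-0.5, 0))
        assert np.abs(out - smooth_image).max() < 1e-6

    def test_single_axis(self, smooth_image):
        row = smooth_image[0]
        out = apply_fourier_shift(row, (4,), axes=(-1,))
        assert np.allclose(out, np.roll(row, 4), atol=1e-9)


class TestPhaseCorrelate:
    def test_identical_images(self, smooth_image):
        shift, score = phase_correlate(smooth_image, smooth_image, 10)
        assert shift == (0, 0)
        # peak height of the normalized cross-power equals the occupied
        # spectral fraction for identical band-limited images
        assert score > 0.1

    def test_recovers_cyclic_shift(self, smooth_image):
        b = np.roll(smooth_image, (5, -3), axis=(0, 1))
        shift, _ = phase_correlate(smooth_image, b, 10)
        assert shift == (5, -3)

    def test_radius_excludes_distant_peak(self, smooth_image):
        """A true shift outside the search window is not reported; the best
        in-window shift comes back with a lower score."""
        b = np.roll(smooth_image, (15, 0), axis=(0, 1))
        (dy, dx), score_far = phase_correlate(smooth_image, b, 4)
        assert max(abs(dy), abs(dx)) <= 4
        _, score_home = phase_correlate(smooth_image, b, 20)
        assert score_far < score_home

    def test_constant_image_rejected(self):
        flat = np.ones((32, 32))
        with pytest.raises(ValueError, match="uninformative|constant"):
            phase_correlate(flat, flat, 5)

    def test_agrees_with_skimage_oracle(self, smooth_image):
        from skimage.registration import phase_cross_correlation

        b = np.roll(smooth_image, (4, -6), axis=(0, 1))
        ours, _ = phase_correlate(smooth_image, b, 10)
        ref, _, _ = phase_cross_correlation(smooth_image, b, upsample_factor=1)
        # skimage reports the shift to apply to b to match a (opposite sign)
        assert (round(-ref[0]), round(-ref[1])) == ours


class TestSubpixelRefine:
    def test_upsample_one_returns_integer(self, smooth_image):
        b = np.roll(smooth_image, (2, 1), axis=(0, 1))
        assert subpixel_refine(smooth_image, b, (2, 1), 1) == (2.0, 1.0)

    def test_recovers_injected_fractional_shift(self, smooth_image):
        true = (2.25, -0.5)
        b = apply_fourier_shift(smooth_image, true)
        integer, _ = phase_correlate(smooth_image, b, 8)
        dy, dx = subpixel_refine(smooth_image, b, integer, 100)
        assert abs(dy - true[0]) < 0.05 and abs(dx - true[1]) < 0.05

    def test_fixed_point_after_unshifting(self, smooth_image):
        true = (1.3, -2.7)
        b = apply_fourier_shift(smooth_image, true)
        integer, _ = phase_correlate(smooth_image, b, 8)
        est = subpixel_refine(smooth_image, b, integer, 100)
        b_back = apply_fourier_shift(b, (-est[0], -est[1]))
        residual, _ = phase_correlate(smooth_image, b_back, 4)
        assert residual == (0, 0)

    def test_agrees_with_skimage_oracle(self, smooth_image):
        from skimage.registration import phase_cross_correlation

        b = apply_fourier_shift(smooth_image, (0.8, -1.4))
        integer, _ = phase_correlate(smooth_image, b, 8)
        ours = subpixel_refine(smooth_image, b, integer, 50)
        ref, _, _ = phase_cross_correlation(smooth_image, b, upsample_factor=50)
        assert abs(-ref[0] - ours[0]) < 0.05 and abs(-ref[1] - ours[1]) < 0.05


class TestRegisterGrid:
    def test_zero_jitter_refines_to_nominal(self, tiny_scan_clean):
        grid = tiny_scan_clean["grid"]
        table = register_grid(tiny_scan_clean["tiles"], grid, 0)
        for t, (dy, dx) in table.right.items():
            assert abs(dy) < 0.05 and abs(dx - grid.step_x) < 0.05
        for t, (dy, dx) in table.bottom.items():
            assert abs(dy - grid.step_y) < 0.05 and abs(dx) < 0.05

    def test_recovers_injected_jitter(self, jitter_scan):
        """Pairwise displacements on noisy tiles within 0.2 px of truth."""
        grid = jitter_scan["grid"]
        truth = jitter_scan["truth"]
        table = register_grid(jitter_scan["tiles"], grid, [0, 1])
        errs = []
        for t, d in table.right.items():
            td = truth.relative_shift(t, TileIndex(t.iy, t.ix + 1))
            errs.append(np.abs(np.subtract(d, td)))
        for t, d in table.bottom.items():
            td = truth.relative_shift(t, TileIndex(t.iy + 1, t.ix))
            errs.append(np.abs(np.subtract(d, td)))
        assert np.max(errs) < 0.2

    def test_noise_free_recovery_tighter(self, jitter_scan):
        grid = jitter_scan["grid"]
        truth = jitter_scan["truth_clean"]
        table = register_grid(jitter_scan["tiles_clean"], grid, 0)
        errs = []
        for t, d in table.right.items():
            errs.append(np.abs(np.subtract(
                d, truth.relative_shift(t, TileIndex(t.iy, t.ix + 1)))))
        for t, d in table.bottom.items():
            errs.append(np.abs(np.subtract(
                d, truth.relative_shift(t, TileIndex(t.iy + 1, t.ix)))))
        assert np.max(errs) < 0.05

    def test_featureless_pair_flagged_and_nominal_retained(self):
        grid = MosaicGrid(n_x=2, n_y=1, N_x=32, N_y=32, N_theta=1,
                          nominal_overlap_x=8, nominal_overlap_y=8)
        flat_tiles = {TileIndex(0, 0): np.full((1, 32, 32), 0.5),
                      TileIndex(0, 1): np.full((1, 32, 32), 0.5)}
        with pytest.warns(UserWarning, match="nominal"):
            table = register_grid(flat_tiles, grid, 0)
        assert table.right[TileIndex(0, 0)] == (0.0, float(grid.step_x))
        assert table.score_right[TileIndex(0, 0)] == 0.0

    def test_narrow_overlap_skipped_with_warning(self):
        grid = MosaicGrid(n_x=2, n_y=1, N_x=32, N_y=32, N_theta=1,
                          nominal_overlap_x=4, nominal_overlap_y=4)
        rng = np.random.default_rng(0)
        tiles = {TileIndex(0, 0): rng.random((1, 32, 32)),
                 TileIndex(0, 1): rng.random((1, 32, 32))}
        with pytest.warns(UserWarning, match="narrower"):
            table = register_grid(tiles, grid, 0)
        assert np.isnan(table.score_right[TileIndex(0, 0)])


class TestSolvePositions:
    def test_single_tile_anchor(self):
        table = ShiftTable(n_y=1, n_x=1)
        origins = solve_positions(table)
        assert origins[TileIndex(0, 0)] == (0.0, 0.0)

    def test_exact_consistent_shifts(self):
        table = ShiftTable(n_y=2, n_x=2)
        table.right = {TileIndex(0, 0): (0.5, 40.0), TileIndex(1, 0): (0.5, 40.0)}
        table.bottom = {TileIndex(0, 0): (38.0, -0.25), TileIndex(0, 1): (38.0, -0.25)}
        origins = solve_positions(table)
        assert origins[TileIndex(0, 1)] == pytest.approx((0.5, 40.0))
        assert origins[TileIndex(1, 0)] == pytest.approx((38.0, -0.25))
        assert origins[TileIndex(1, 1)] == pytest.approx((38.5, 39.75))
        res = table.loop_residuals[TileIndex(0, 0)]
        assert res == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_perturbed_cell_residual_equals_injected_inconsistency(self):
        table = ShiftTable(n_y=2, n_x=2)
        table.right = {TileIndex(0, 0): (0.0, 40.0), TileIndex(1, 0): (0.0, 40.0)}
        table.bottom = {TileIndex(0, 0): (38.0, 0.0),
                        TileIndex(0, 1): (38.0 + 0.6, 0.0 - 0.2)}
        solve_positions(table)
        res = table.loop_residuals[TileIndex(0, 0)]
        assert res == pytest.approx((0.6, -0.2))

    def test_disconnected_grid_rejected(self):
        table = ShiftTable(n_y=1, n_x=2)  # no right entry at all
        with pytest.raises(ValueError, match="disconnected"):
            solve_positions(table)

    def test_origins_reproduce_pairwise_shifts(self, jitter_scan):
        grid = jitter_scan["grid"]
        table = register_grid(jitter_scan["tiles_clean"], grid, 0)
        origins = solve_positions(table)
        for t, d in table.right.items():
            nb = TileIndex(t.iy, t.ix + 1)
            got = np.subtract(origins[nb], origins[t])
            assert np.abs(got - d).max() < 0.25  # averaging over loop residuals


class TestShiftTableText:
    def test_roundtrip_to_printed_precision(self, jitter_scan):
        table = register_grid(jitter_scan["tiles_clean"], jitter_scan["grid"], 0)
        back = ShiftTable.from_text(table.to_text())
        assert back.n_y == table.n_y and back.n_x == table.n_x
        for t, d in table.right.items():
            assert back.right[t] == pytest.approx(d, abs=0.005)
        for t, d in table.bottom.items():
            assert back.bottom[t] == pytest.approx(d, abs=0.005)

    def test_border_tiles_have_none_placeholders(self):
        table = ShiftTable(n_y=1, n_x=2, right={TileIndex(0, 0): (0.0, 40.0)})
        text = table.to_text()
        last = text.strip().splitlines()[-1]
        assert last.split() == ["0", "1", "none", "none", "none", "none"]
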