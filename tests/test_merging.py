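"""Seam blending, panorama assembly, and sinogram-row stitching."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mosaictomo import (
    AcquisitionGeometry,
    MosaicGrid,
    OverlapSpec,
    TileIndex,
    blend_pair,
    forward_project,
    make_phantom,
    panorama_projections,
    random_spheres_spec,
    simulate_soa_scan,
    stitch_panorama,
    stitch_sinogram_row,
)
from conftest import NOISE_FREE


class TestBlendPair:
    def test_identical_content_is_exact(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 88))
        for method in ("pyramid", "feather", "max", "min"):
            out = blend_pair(img[:, :60], img[:, 28:],
                             OverlapSpec("horizontal", 32, method))
            assert np.abs(out - img).max() < 1e-12, method

    def test_constant_pair_monotone_transition(self):
        a = np.full((8, 60), 0.2)
        b = np.full((8, 60), 0.8)
        out = blend_pair(a, b, OverlapSpec("horizontal", 16, "pyramid"))
        assert out.shape == (8, 104)
        assert out[0, 0] == 0.2 and out[0, -1] == 0.8
        assert np.all(np.diff(out[0]) >= -1e-12)
        # energy bounds: never outside [min, max] of the inputs
        assert out.min() >= 0.2 - 1e-9 and out.max() <= 0.8 + 1e-9

    def test_max_min_comparators(self):
        a = np.full((4, 20), 0.2)
        b = np.full((4, 20), 0.8)
        hi = blend_pair(a, b, OverlapSpec("horizontal", 8, "max"))
        lo = blend_pair(a, b, OverlapSpec("horizontal", 8, "min"))
        assert np.all(hi[:, 12:20] == 0.8)
        assert np.all(lo[:, 12:20] == 0.2)

    def test_feather_bounds_on_constants(self):
        a = np.full((4, 20), 0.2)
        b = np.full((4, 20), 0.8)
        out = blend_pair(a, b, OverlapSpec("horizontal", 8, "feather"))
        assert out.min() >= 0.2 - 1e-9 and out.max() <= 0.8 + 1e-9
        assert np.all(np.diff(out[0]) >= -1e-12)

    def test_seam_quality_ordering(self):
        """Pyramid spreads a brightness step most gently:
        pyramid < feather < max/min in seam gradient."""
        rng = np.random.default_rng(5)
        base = gaussian_filter(rng.normal(size=(96, 288)), 2)
        base = 0.005 * base / base.std()
        t1 = 0.45 + base[:, :160]
        t2 = 0.55 + base[:, 128:]
        grad = {}
        for m in ("pyramid", "feather", "max", "min"):
            out = blend_pair(t1, t2, OverlapSpec("horizontal", 32, m))
            prof = np.abs(np.diff(out, axis=1)).mean(axis=0)
            grad[m] = prof[120:168].max()
        assert grad["pyramid"] < grad["feather"] < min(grad["max"], grad["min"])

    def test_outside_overlap_equals_inputs_exactly(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((16, 40)), rng.random((16, 30))
        out = blend_pair(a, b, OverlapSpec("horizontal", 10, "pyramid"))
        assert np.array_equal(out[:, :30], a[:, :30])
        assert np.array_equal(out[:, 40:], b[:, 10:])

    def test_vertical_axis(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((30, 16)), rng.random((20, 16))
        out = blend_pair(a, b, OverlapSpec("vertical", 8, "feather"))
        assert out.shape == (42, 16)
        assert np.array_equal(out[:22], a[:22])

    def test_zero_overlap_pyramid_abuts_with_warning(self):
        a = np.zeros((4, 8))
        b = np.ones((4, 8))
        with pytest.warns(UserWarning, match="abutment"):
            out = blend_pair(a, b, OverlapSpec("horizontal", 0, "pyramid"))
        assert out.shape == (4, 16)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="blend method"):
            OverlapSpec("horizontal", 4, "average")

    def test_pyramid_identity_any_depth(self):
        """Blending an image with itself is the identity for all overlap widths."""
        rng = np.random.default_rng(3)
        img = rng.random((24, 128))
        for ov in (4, 8, 16, 32, 64):
            out = blend_pair(img[:, :96], img[:, 96 - ov:],
                             OverlapSpec("horizontal", ov, "pyramid"))
            assert np.abs(out - img).max() < 1e-6, ov


class TestStitchPanorama:
    def test_single_tile_is_identity(self):
        grid = MosaicGrid(n_x=1, n_y=1, N_x=32, N_y=24, N_theta=1)
        rng = np.random.default_rng(0)
        img = rng.random((24, 32))
        pano = stitch_panorama({TileIndex(0, 0): img},
                               {TileIndex(0, 0): (0.0, 0.0)}, grid)
        assert np.allclose(pano.image, np.clip(img, 0, 1))
        assert np.all(pano.footprint == 1)

    def test_width_bookkeeping(self, tiny_scan_clean):
        grid = tiny_scan_clean["grid"]
        origins = {t: grid.nominal_origin(t) for t in grid.tiles()}
        norm = {t: tiny_scan_clean["tiles"][t].data[0] for t in origins}
        pano = stitch_panorama(norm, origins, grid)
        assert pano.image.shape == (grid.panorama_height, grid.panorama_width)
        ov = grid.nominal_overlap_x
        assert np.sum(pano.footprint[0] == 2) == ov * (grid.n_x - 1)

    def test_matches_wide_detector_oracle(self):
        """A noise-free 2x1 mosaic panorama reproduces the projection a single
        wide detector would have recorded."""
        grid = MosaicGrid(n_x=2, n_y=1, N_x=64, N_y=64, N_theta=1,
                          nominal_overlap_x=16, nominal_overlap_y=0)
        h, w = grid.panorama_height, grid.panorama_width
        spec = random_spheres_spec((h, w, 48), 40, radius_range=(3, 8),
                                   value_range=(0.01, 0.03), seed=3,
                                   inscribed=False)
        phantom = make_phantom(spec)
        geom = AcquisitionGeometry((0.0,))
        proj = panorama_projections(phantom, grid, geom)
        tiles, truth = simulate_soa_scan(None, grid, dict(NOISE_FREE, jitter_px=0.0),
                                         geometry=geom, projections=proj)
        origins = truth.true_origins
        pano = stitch_panorama({t: tiles[t].data[0] for t in tiles}, origins, grid)
        ideal = np.clip(np.exp(-proj[0]), 0, 1)
        rms = np.sqrt(np.mean((pano.image - ideal) ** 2))
        assert rms < 1e-3

    def test_inconsistent_tile_shapes_rejected(self):
        grid = MosaicGrid(n_x=2, n_y=1, N_x=16, N_y=16, N_theta=1,
                          nominal_overlap_x=4)
        tiles = {TileIndex(0, 0): np.zeros((16, 16)),
                 TileIndex(0, 1): np.zeros((16, 18))}
        origins = {t: grid.nominal_origin(t) for t in tiles}
        with pytest.raises(ValueError, match="shape"):
            stitch_panorama(tiles, origins, grid)


class TestStitchSinogramRow:
    def test_single_column_grid_returns_tile_row(self, tiny_scan_clean):
        grid = MosaicGrid(n_x=1, n_y=1, N_x=48, N_y=48, N_theta=8)
        tile = tiny_scan_clean["tiles"][TileIndex(0, 0)]
        sino = stitch_sinogram_row({TileIndex(0, 0): tile.data},
                                   {TileIndex(0, 0): (0.0, 0.0)}, 20, grid)
        assert np.array_equal(sino, np.clip(tile.data[:, 20, :], 0, 1))

    def test_matches_wbm_row_with_integer_shifts(self, tiny_scan_clean):
        """The central mode-equivalence regression: with integral vertical
        origins the stitched sinogram row is bit-identical to the same row of
        the per-angle panorama stack."""
        grid = tiny_scan_clean["grid"]
        tiles = tiny_scan_clean["tiles"]
        origins = {t: grid.nominal_origin(t) for t in grid.tiles()}
        stacks = {t: np.clip(tiles[t].data, 0, 1) for t in tiles}
        y = 20
        sino = stitch_sinogram_row(stacks, origins, y, grid, method="pyramid")
        for k in range(grid.N_theta):
            pano = stitch_panorama({t: stacks[t][k] for t in stacks}, origins,
                                   grid, "pyramid")
            assert np.array_equal(sino[k], pano.image[y]), f"angle {k}"

    def test_out_of_range_slice_rejected(self, tiny_scan_clean):
        grid = tiny_scan_clean["grid"]
        origins = {t: grid.nominal_origin(t) for t in grid.tiles()}
        stacks = {t: v.data for t, v in tiny_scan_clean["tiles"].items()}
        with pytest.raises(ValueError, match="outside"):
            stitch_sinogram_row(stacks, origins, 500, grid)
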