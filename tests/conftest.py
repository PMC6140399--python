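"""Shared fixtures: small simulated mosaic scans, generated once per session.

All data is synthetic and produced at run time by the package's own
simulator with fixed seeds; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from mosaictomo import (
    AcquisitionGeometry,
    CenterTable,
    MergedDataset,
    MosaicGrid,
    MosaicLayout,
    make_phantom,
    panorama_projections,
    random_spheres_spec,
    register_grid,
    simulate_soa_scan,
    solve_positions,
    stitch_panorama,
    neg_log,
    reconstruct_wbm,
    scan_center,
)

NOISE_FREE = {
    "poisson": False,
    "quantize": False,
    "scale_drift": 0.0,
    "flat_counts": 1.0,
    "dark_counts": 0.0,
    "flat_gradient": 0.0,
}


def disk_sinogram(disks, width, angles_deg, center):
    """Analytic parallel-beam sinogram of y-aligned disks (chord lengths).

    Independent of the package's forward projector: each disk of radius r
    and attenuation mu centred at (x, z) contributes mu * 2*sqrt(r^2 - d^2)
    at signed detector distance d from its projected centre.
    """
    t = np.arange(width, dtype=float)
    out = np.zeros((len(angles_deg), width))
    for k, ang in enumerate(np.deg2rad(angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        for (cx, cz, r, mu) in disks:
            t0 = center + (cx - center) * c + (cz - center) * s
            d2 = r * r - (t - t0) ** 2
            out[k] += mu * 2.0 * np.sqrt(np.clip(d2, 0.0, None))
    return out


@pytest.fixture(scope="session")
def tiny_grid():
    return MosaicGrid(n_x=2, n_y=2, N_x=48, N_y=48, N_theta=8,
                      nominal_overlap_x=12, nominal_overlap_y=12)


@pytest.fixture(scope="session")
def tiny_scan(tiny_grid):
    """Noisy 2x2 scan of a small phantom, with cached projections and truth."""
    h, w = tiny_grid.panorama_height, tiny_grid.panorama_width
    spec = random_spheres_spec((h, w, w), 14, radius_range=(4, 9),
                               value_range=(0.005, 0.015), seed=5,
                               inscribed=True, margin=0.15)
    phantom = make_phantom(spec)
    geom = AcquisitionGeometry.uniform(tiny_grid.N_theta)
    proj = panorama_projections(phantom, tiny_grid, geom)
    tiles, truth = simulate_soa_scan(phantom, tiny_grid, {"jitter_px": 1.0},
                                     seed=2, geometry=geom, projections=proj)
    return {"grid": tiny_grid, "phantom": phantom, "geometry": geom,
            "projections": proj, "tiles": tiles, "truth": truth}


@pytest.fixture(scope="session")
def tiny_scan_clean(tiny_scan):
    """Noise-free, zero-jitter variant of the tiny scan (same projections)."""
    params = dict(NOISE_FREE, jitter_px=0.0)
    tiles, truth = simulate_soa_scan(None, tiny_scan["grid"], params, seed=2,
                                     geometry=tiny_scan["geometry"],
                                     projections=tiny_scan["projections"])
    return {"tiles": tiles, "truth": truth, "grid": tiny_scan["grid"],
            "projections": tiny_scan["projections"],
            "geometry": tiny_scan["geometry"]}


@pytest.fixture(scope="session")
def jitter_scan():
    """2x2 mosaic of 128^2 tiles with sub-pixel jitter over a textured slab.

    Two adjacent angles of a dense scan; used for registration recovery at
    moderate scale.
    """
    grid = MosaicGrid(n_x=2, n_y=2, N_x=128, N_y=128, N_theta=2,
                      nominal_overlap_x=24, nominal_overlap_y=24)
    h, w = grid.panorama_height, grid.panorama_width
    spec = random_spheres_spec((h, w, 96), 260, radius_range=(3, 9),
                               value_range=(0.008, 0.03), seed=11,
                               inscribed=False)
    phantom = make_phantom(spec)
    geom = AcquisitionGeometry((0.0, 0.04))
    proj = panorama_projections(phantom, grid, geom)
    tiles, truth = simulate_soa_scan(phantom, grid, {"jitter_px": 2.0},
                                     seed=8, geometry=geom, projections=proj)
    clean, truth_clean = simulate_soa_scan(None, grid, dict(NOISE_FREE, jitter_px=2.0),
                                           seed=8, geometry=geom, projections=proj)
    return {"grid": grid, "geometry": geom, "projections": proj,
            "tiles": tiles, "truth": truth,
            "tiles_clean": clean, "truth_clean": truth_clean}


@pytest.fixture(scope="session")
def e2e():
    """Full pipeline on a 2x2 mosaic: simulate, register, stitch, calibrate,
    reconstruct; everything the whole-block acceptance checks need."""
    from mosaictomo.core_model import TileIndex

    grid = MosaicGrid(n_x=2, n_y=2, N_x=64, N_y=64, N_theta=180,
                      nominal_overlap_x=16, nominal_overlap_y=16)
    h, w = grid.panorama_height, grid.panorama_width
    spec = random_spheres_spec((h, w, w), 25, radius_range=(4, 9),
                               value_range=(0.005, 0.015), seed=21,
                               inscribed=True, margin=0.15)
    phantom = make_phantom(spec)
    geom = AcquisitionGeometry.uniform(grid.N_theta)
    proj = panorama_projections(phantom, grid, geom)
    tiles, truth = simulate_soa_scan(phantom, grid,
                                     {"jitter_px": 1.0, "flat_counts": 5000.0},
                                     seed=4, geometry=geom, projections=proj)

    table = register_grid(tiles, grid, [0, 1])
    origins = solve_positions(table)
    layout = MosaicLayout.from_origins(origins, grid)
    norm = {t: tiles[t].normalized() for t in tiles}
    panos = [stitch_panorama({t: norm[t][k] for t in norm}, origins, grid,
                             "pyramid").image for k in range(geom.n_theta)]
    merged = MergedDataset(data=np.stack(panos), theta=np.array(geom.angles_deg))

    anchor = truth.true_origins[TileIndex(0, 0)]
    expected_center = truth.center - anchor[1] - layout.x_start
    cands = np.arange(round(expected_center) - 10, round(expected_center) + 11,
                      dtype=float)
    centers = CenterTable()
    for row in range(grid.n_y):
        y = layout.row_y0[row] + grid.N_y // 2
        sino = neg_log(np.asarray(merged.data[:, y, :], dtype=float))
        centers.centers[row] = scan_center(sino, cands, angles_deg=merged.theta,
                                           keep_reconstructions=False).c_opt
    slices = reconstruct_wbm(merged, centers, range(merged.data.shape[1]),
                             layout=layout)
    volume = np.stack([s.image for s in slices])
    return {"grid": grid, "phantom": phantom, "geometry": geom, "tiles": tiles,
            "truth": truth, "table": table, "origins": origins, "layout": layout,
            "norm": norm, "merged": merged, "centers": centers, "volume": volume,
            "expected_center": expected_center, "projections": proj}
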