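# mosaictomo

Mosaic ("beyond field-of-view") parallel-beam X-ray tomography at desk
scale: simulate or ingest tile datasets from a sinogram-oriented
acquisition, register and blend the tiles, calibrate rotation centers by
entropy minimization, and reconstruct slices in whole-block or single-slice
mode.

## The problem

Synchrotron beams are millimetres wide, but interesting specimens — a
charcoal pellet, an embedded mouse brain — are centimetres.  To image an
object larger than the beam and detector without losing resolution, the
rotation axis is moved through an `n_y x n_x` grid of offsets relative to
the field of view and a complete 180° rotation series is collected at each
offset (*sinogram-oriented acquisition*, SOA).  Each such "ring dataset" is
complete in angle and incomplete in detector column.  Ignoring overlaps,
the reconstructed object then holds

    N_voxel = (n_x N_x)^2 * (n_y N_y)

voxels for `N_x x N_y`-pixel tiles — teravoxels at beamline scale.  This
package implements the full processing chain for such data and a simulator
that emulates the acquisition with known ground truth, so every stage is
testable on a desktop:

1. **Registration** — commanded tile positions are refined pairwise by
   phase correlation (peak of the normalized cross-power spectrum within a
   limited search radius) with sub-pixel precision `~1/100` px from local
   matrix-DFT upsampling; sub-pixel shifts are applied via the Fourier
   shift theorem.
2. **Stitching & blending** — per-angle panoramas (whole-block mode, WBM)
   or per-slice sinograms (single-slice mode, SSM), with Laplacian-pyramid
   seam blending: each spatial-frequency band transitions over a
   scale-matched distance, so brightness mismatches between tiles leave no
   visible seam and no ring artifacts.
3. **Center calibration** — per grid row, the rotation-center abscissa `c`
   is found by scanning candidates and minimizing the reconstruction's
   histogram entropy `S = -sum_i p_i ln p_i`; a mis-set center smears
   features into arcs and measurably widens the gray-level distribution.
4. **Reconstruction** — ramp-filtered backprojection (Shepp–Logan
   apodization, pluggable gridrec-style backend), Beer–Lambert
   linearization, optional single-material transport-of-intensity phase
   filter, and a deterministic work partition whose per-rank results
   concatenate to the serial result bit for bit.

Tile data live in a DataExchange-style HDF5 layout (`/exchange/data`,
`data_white`, `data_dark`, `theta`; one file per grid position, named
`{prefix}_y{YY}_x{XX}.h5`), with flat/dark normalization and n-fold binning
provided.

## Worked example

Simulate a 2×2 mosaic scan (64² tiles, 16 px overlap, 90 angles, ±1 px
stage jitter), register it, stitch, calibrate and reconstruct one slice:

```python
import numpy as np
from mosaictomo import *

grid = MosaicGrid(n_x=2, n_y=2, N_x=64, N_y=64, N_theta=90,
                  nominal_overlap_x=16, nominal_overlap_y=16)
print(f"panorama: {grid.panorama_height} x {grid.panorama_width} px,",
      f"{total_voxels(grid):,} voxels ignoring overlaps")

h, w = grid.panorama_height, grid.panorama_width
phantom = make_phantom(random_spheres_spec((h, w, w), 60, seed=33,
                                           value_range=(0.006, 0.018),
                                           radius_range=(5, 12), margin=0.08))
tiles, truth = simulate_soa_scan(phantom, grid, {"jitter_px": 1.0}, seed=4)

table = register_grid(tiles, grid, angle_selection=[0, 1])
origins = solve_positions(table)
print(table.to_text())

norm = {t: tiles[t].normalized() for t in tiles}
lay = MosaicLayout.from_origins(origins, grid)
panos = [stitch_panorama({t: norm[t][k] for t in norm}, origins, grid,
                         "pyramid").image for k in range(grid.N_theta)]
merged = MergedDataset(np.stack(panos), np.arange(90) * 2.0)

centers = CenterTable()
for row in range(grid.n_y):
    y = lay.row_y0[row] + grid.N_y // 2
    sino = neg_log(np.asarray(merged.data[:, y, :], float))
    centers.centers[row] = scan_center(sino, np.arange(45.0, 66.0),
                                       angles_deg=merged.theta,
                                       keep_reconstructions=False).c_opt
print(centers.to_text())

slice40 = reconstruct_wbm(merged, centers, [40], layout=lay)[0].image
print(f"slice 40: {slice40.shape}, attenuation range "
      f"[{slice40.min():.4f}, {slice40.max():.4f}]")
```

Output:

```
panorama: 112 x 112 px, 2,097,152 voxels ignoring overlaps
# iy ix dy_right dx_right dy_bottom dx_bottom
0 0 0.25 48.02 49.32 -0.49
0 1 none none 49.11 -0.94
1 0 0.23 47.41 none none
1 1 none none none none

# row center
0 56.00
1 56.00

slice 40: (111, 111), attenuation range [-0.0041, 0.0194]
```

Reading the shift table: the right-neighbour displacement of tile (0, 0) is
48.02 px — the commanded 48 px pitch (64 − 16 overlap) plus the recovered
sub-pixel stage error; the bottom displacements (49.32, 49.11 px) show the
~1 px vertical jitter the simulator injected, recovered to better than
0.2 px.  Both grid rows calibrate to center 56, the panorama midline, and
the reconstructed slice recovers the spheres' attenuation (up to 0.018 per
voxel, plus small filter overshoot around edges).

The same pipeline is scriptable from a shell:

```sh
mosaictomo simulate --out run --grid-shape 2 2 --tile-shape 64 64 \
    --overlap 16 --n-theta 90 --jitter 1 --seed 4
mosaictomo register --dir run --grid-shape 2 2 --overlap 16 \
    --angle 0 --angle 1 --out run/shifts.txt
mosaictomo merge --dir run --grid-shape 2 2 --overlap 16 \
    --shifts run/shifts.txt --out run/merged.h5
mosaictomo center --merged run/merged.h5 --row 0 --slice 32 --from 45 --to 65
mosaictomo recon --mode wbm --merged run/merged.h5 --centers centers.txt \
    --slices 30:60 --out run/recon
```

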