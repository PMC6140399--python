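# Methods

`mosaictomo` implements the processing chain for mosaic ("beyond
field-of-view") parallel-beam X-ray tomography under sinogram-oriented
acquisition (SOA): the specimen is wider and taller than the beam and
detector, so the rotation axis is placed at a grid of lateral/vertical
offsets relative to the field of view, and a complete 180° rotation series
("ring dataset") is collected at each offset.  Each ring dataset is complete
in angle and incomplete in detector column; the pipeline's job is to refine
the commanded tile positions, stitch and blend the tiles, calibrate the
rotation center, and reconstruct slices.

## Geometry and conventions

All indices are 0-based with half-open intervals.  The detector frame has
its origin at the top-left pixel, `y` down (parallel to the rotation axis),
`x` right; projection stacks are ordered `(theta, y, x)`.  The object is
rotated about the vertical axis; the beam travels along `z`; reconstructed
slices are square maps in the `x`–`z` plane with the rotation axis at
`(c, c)` where `c` is the calibrated center abscissa.  Angles are sampled on
the half-open interval `theta_k = k * 180 / N_theta` degrees, because 0° and
180° are redundant in a parallel beam.  Tile files are named
`{prefix}_y{YY}_x{XX}.h5` with two-digit zero-padded grid indices counting
from zero, which caps the scheme at 100 tiles per direction.

## Synthetic acquisition

The simulator stands in for a beamline and defines the package's study
conditions.  Its photon model is pure attenuation,

    I = I_flat * s_tile * exp(-∫ mu ds) + I_dark (+ Poisson noise),

quantized to 16-bit unsigned counts.  Propagation phase contrast is *not*
simulated; the transport-of-intensity phase filter is therefore an
approximately identity-compatible step on synthetic data and is off by
default, with all parameters exposed for real data.

Line integrals are computed once on a virtual detector spanning the whole
mosaic, by rotating the voxelized phantom about the axis with cubic-spline
interpolation (the spline prefilter runs once per volume, not per angle) and
summing along the beam.  Each tile is then a window of these projections at
its *true* origin = commanded origin + stage jitter; the fractional part of
the window position is applied with the Fourier shift theorem so that
overlapping tiles are exactly consistent samples of one band-limited
function, as they are for a real rigid specimen.  Jitter is drawn uniformly
from `[-j, j]` per axis once per tile (SOA moves the stage once per ring
dataset, so the offset is constant over that tile's angles).  Per-tile
white/dark frames, a smooth low-order flat-field pattern, a per-tile
multiplicative intensity drift, and Poisson counting noise complete the
model.  All randomness flows from a single seed through per-tile
substreams.

Defaults (the study conditions): flat level 5000 counts/pixel, dark level
100 counts, 20 white + 10 dark frames per tile, 2% intensity-scale drift,
3 px jitter bound, 5% flat-field pattern amplitude.  Sphere attenuation
values in the bundled phantom generator (0.005–0.03 per voxel path length)
are chosen so that typical line integrals are of order 0.1–1, i.e.
transmissions from ~0.3 to ~1 — the regime a sample sized for tomography
(mean transmission near 1/e) actually produces.  The generator can place
spheres either inside the inscribed cylinder (for reconstruction studies,
where truncation must be avoided) or uniformly over the whole box (for
registration studies, where every overlap strip must carry texture — an
alignment problem with featureless seams is ill-posed for any method).

What the simulator does *not* emulate: phase fringes, detector
point-spread, scintillator blur, ring-artifact-inducing fixed-pattern
noise, beam-intensity drift within one rotation series, and rotation-axis
wobble.  Passing tests therefore demonstrate the correctness of the
pipeline's geometry, statistics and numerics, not robustness to every
instrumental effect of a real beamline.

## Registration

Commanded positions are refined pairwise: for every horizontally and
vertically adjacent tile pair the nominal overlap strips are extracted from
one normalized projection (or the average of several user-selected angles —
averaging adjacent angles of a dense scan is the recommended noise-robust
setting, since the tile offset is constant over the ring dataset while the
photon noise is independent per angle).

Each pair is measured by phase correlation: the peak of the normalized
cross-power spectrum, searched only within a limited radius (default 10 px)
of zero residual shift because the commanded positions are approximately
correct and the periodic correlation map is otherwise ambiguous.  Sub-pixel
resolution (default 1/100 px) comes from a local matrix-multiply DFT
upsampling of the cross-power surface around the integer peak.

Two implementation details matter for accuracy on narrow strips and are the
package's own choices:

* strips are detrended (mean-subtracted), Hann-windowed and zero-padded
  before correlation, so the measurement is a linear, not cyclic,
  correlation of the shared content;
* the measurement runs twice: the second pass re-centers one strip by the
  first estimate (Fourier shift) and measures the small remaining
  correction.  At zero residual the edge-truncation bias of a windowed
  strip is symmetric and cancels; this removes the few-hundredths-of-a-pixel
  bias a single pass leaves when the residual is a sizeable fraction of the
  strip width.

Degenerate (featureless) overlaps raise an internal error that is caught:
the pair is flagged, the nominal shift retained, and the pair's score set
to zero.  Overlaps narrower than 8 px are skipped with a warning.

Absolute tile origins are solved by anchoring tile (0, 0) at the origin and
averaging the left-neighbour and top-neighbour path accumulations per tile;
loop-closure residuals are reported per 2×2 cell as a consistency
diagnostic.  The shift table is exported as text (`iy ix dy_right dx_right
dy_bottom dx_bottom`, `none` on borders, two decimals).

## Stitching and blending

Tiles are placed at integer canvas positions with the fractional remainder
applied via the Fourier shift theorem; horizontal seams are blended within
each grid row, then row strips are blended vertically.  Four seam methods
are provided: `pyramid` (default), `feather` (a single Gaussian-profile
mask of width overlap/8 at the original scale — deliberately a "harder"
transition), and the `max`/`min` comparators.

Pyramid blending decomposes the two overlap strips into Laplacian pyramids
and recombines them level-wise with a Gaussian-pyramid transition mask whose
finest level is a hard step at the seam midline: low spatial frequencies
transition over the whole overlap, fine structure switches at the seam.
Two design choices differ from the textbook construction:

* **1-D pyramids along the seam normal.**  The pyramids decimate only along
  the blend axis and are vectorized over the seam-parallel axis.  For a
  horizontal seam the blend is then exactly row-separable, which is what
  makes single-slice-mode sinogram stitching reproduce whole-block rows *bit
  for bit* when the vertical alignment is integral — the pipeline's central
  mode-equivalence regression.  A full 2-D pyramid mixes detector rows and
  cannot satisfy that property.
* **Depth `floor(log2(overlap)) - 2`, clamped to [1, 8].**  The coarsest
  mask level keeps ≥ ~4 samples across the overlap so it still resolves its
  0 → 1 boundary; reducing all the way to one sample averages the mask to
  1/2 and pushes the low-frequency transition to the overlap *edges*
  instead of spreading it across the seam (measurably worse seam
  gradients).

The blended canvas equals the sole contributing input exactly outside the
overlap.  Blending two strips of identical content is the identity to
floating-point round-off; on constant inputs the output is monotone between
the two levels and never exceeds their range.  Merged panoramas are stored
as 32-bit floats in [0, 1] in the same HDF5 dialect as tiles.

Single-slice mode rounds vertical origins to whole pixels (sub-pixel
alignment in `x` only), extracts one detector row per ring dataset and
blends along `x` with the same overlaps and method as the panorama path.
When a slice row falls inside a vertical overlap, the lower grid row's data
is used.

## Rotation-center calibration

One center per mosaic grid row, by entropy minimization: the slice is
reconstructed at each candidate center and the Shannon entropy
`S = -Σ p_i ln p_i` of its grayscale histogram is evaluated; artifacts from
a mis-set center widen the gray-level distribution and raise `S`, so the
scan's argmin is the calibrated center (ties break toward the smaller
abscissa).  Numerical choices: 1024 bins over the global min/max of *all*
candidate reconstructions (a shared range is required for comparability);
the histogram is restricted to the inscribed circular field of view so
out-of-field corners do not dominate; candidates are integers by default
with an optional 0.25-px refinement pass; all candidate reconstructions are
retained on the scan object for manual re-examination.

## Reconstruction

Transmission data are linearized with the Beer–Lambert negative log
(values below 1e-6 clamped with a warning).  The built-in filtered
backprojection uses the exact DFT of the band-limited ramp's spatial kernel
(`h[0] = 1/4`, `h[odd k] = -1/(pi k)^2`) — sampling `|f|` directly biases
the DC response and depresses reconstructed values by several percent — an
optional Shepp–Logan apodization window (default), zero-padding to the next
power of two ≥ 2W, and linear-interpolation backprojection over the 180°
angle set about the stated center, scaled by `pi / N_theta`.  The backend is
pluggable: any callable `(sinogram, angles_deg, center) -> slice` (e.g. a
gridrec binding) can substitute the built-in.

Whole-block mode extracts each requested sinogram row from the merged
dataset and reconstructs it with its grid row's center; slices are mutually
independent.  Single-slice mode stitches only the requested rows directly
from the ring datasets — no merged dataset is built or stored.  An optional
single-material transport-of-intensity phase filter
`H(k) = [1 + lambda z (delta/beta) / (4 pi) |k|^2]^(-1)` is available
upstream of the log transform for propagation-enhanced real data.

Work partitioning for multi-process deployment is a deterministic
contiguous-block split per stage (registration: tile pairs; merging:
angles; center calibration: grid rows; reconstruction: slices).  Because
every per-item computation is a pure function, concatenated per-rank
results equal the serial result bit for bit for any rank count; the test
suite checks 1, 2, 4 and 8.  Actual MPI deployment is out of scope — the
partition contract is runtime-agnostic.

## Problem sizes used in tests

Desk-scale stand-ins for beamline data, chosen to exercise every stage:
registration recovery uses a 3×3 mosaic of 256² tiles with 32 px overlap
and ±3 px jitter over a textured slab (four adjacent angles of a dense
scan); the end-to-end fidelity check uses a 2×2 mosaic of 64² tiles, 16 px
overlap, 180 angles, 5000-count flats, and requires volume RMSE < 8% of the
peak attenuation; center calibration is checked on 512-wide analytic
sinograms with a ±10 px scan.  An 8 px overlap proved too narrow for
reliable phase correlation at ±1.5 px jitter (shared strips shrink to a few
pixels), which is why the smallest mosaics use 16 px; this matches the
practical rule that the commanded overlap should be several times the
worst-case stage error.

## Known limitations

* Attenuation-only simulation: the phase-retrieval step is exercised for
  its filter properties (DC gain 1, variance reduction, identity at zero
  distance), not against propagation physics.
* The mosaic layout assumes tiles within one grid row share an integer
  canvas row origin; residual intra-row vertical offsets are applied as
  cyclic Fourier shifts, so a few wrapped rows appear at tile top/bottom
  edges when intra-row vertical jitter is large.  They land inside vertical
  overlap strips for any realistic overlap/jitter ratio.
* Centers are calibrated per grid row only; a tilted rotation axis (center
  varying within a row) is not modelled.
* The entropy scan assumes the artifact-driven entropy increase dominates;
  on nearly empty slices the curve can be flat — scan a feature-rich slice.
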