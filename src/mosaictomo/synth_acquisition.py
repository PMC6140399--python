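"""Synthetic phantoms and a simulated sinogram-oriented mosaic acquisition.

The simulator stands in for a beamline: it forward-projects an attenuation
phantom onto a wide virtual detector, then carves out one full 180-degree
rotation series per mosaic grid position at a fixed lateral/vertical offset
of the field of view relative to the rotation axis (each ring dataset is
complete in angle and incomplete in x).  Stage jitter, per-tile intensity
scale drift, flat/dark frames and Poisson counting noise are injected with
known ground truth so every downstream stage (registration, blending,
center calibration, reconstruction) can be validated against the truth.

The photon model is pure attenuation:
``I = I_flat * scale_tile * exp(-integral mu ds) + dark (+ Poisson noise)``,
quantized to 16-bit unsigned counts.  Propagation phase contrast is not
simulated, so phase retrieval is an approximately identity-compatible step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .core_model import AcquisitionGeometry, MosaicGrid, TileIndex
from .dx_io import TileDataset
from .registration import apply_fourier_shift

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "forward_project",
    "panorama_projections",
    "simulate_soa_scan",
    "random_spheres_spec",
    "default_noise_params",
]


# ---------------------------------------------------------------------------
# Phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of an attenuation phantom.

    ``shape`` is (n_y, n_x, n_z) in voxels; each primitive is a dict with a
    ``kind`` of 'sphere' (center, radius), 'cylinder' (y-axis aligned:
    center, radius, height) or 'box' (center, size), plus a non-negative
    attenuation ``value`` per unit path length (voxel units).  Centers are
    (y, x, z) voxel coordinates.
    """

    shape: tuple
    primitives: tuple = ()
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("phantom shape must be three positive extents")
        if self.background < 0:
            raise ValueError("background attenuation must be >= 0")
        object.__setattr__(self, "primitives", tuple(dict(p) for p in self.primitives))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))


def _primitive_bounds(p: dict) -> tuple:
    cy, cx, cz = p["center"]
    if p["kind"] == "sphere":
        r = p["radius"]
        return (cy - r, cy + r, cx - r, cx + r, cz - r, cz + r)
    if p["kind"] == "cylinder":
        r, h = p["radius"], p["height"]
        return (cy - h / 2, cy + h / 2, cx - r, cx + r, cz - r, cz + r)
    if p["kind"] == "box":
        sy, sx, sz = p["size"]
        return (cy - sy / 2, cy + sy / 2, cx - sx / 2, cx + sx / 2, cz - sz / 2, cz + sz / 2)
    raise ValueError(f"unknown primitive kind {p.get('kind')!r}")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterize a phantom spec into a float32 (n_y, n_x, n_z) attenuation volume.

    A voxel takes the value of the last primitive containing its center.
    Identical specs produce bit-identical volumes.
    """
    ny, nx, nz = spec.shape
    vol = np.full(spec.shape, spec.background, dtype=np.float32)
    yy = np.arange(ny, dtype=np.float32)
    xx = np.arange(nx, dtype=np.float32)
    zz = np.arange(nz, dtype=np.float32)
    for p in spec.primitives:
        if p.get("value", 0.0) < 0:
            raise ValueError("attenuation values must be >= 0")
        lo_y, hi_y, lo_x, hi_x, lo_z, hi_z = _primitive_bounds(p)
        if lo_y < -0.5 or lo_x < -0.5 or lo_z < -0.5 or hi_y > ny - 0.5 or \
                hi_x > nx - 0.5 or hi_z > nz - 0.5:
            raise ValueError(f"primitive {p} extends outside the volume {spec.shape}")
        cy, cx, cz = p["center"]
        # rasterize only inside the primitive's bounding box
        sy0, sy1 = max(int(np.floor(lo_y)), 0), min(int(np.ceil(hi_y)) + 1, ny)
        sx0, sx1 = max(int(np.floor(lo_x)), 0), min(int(np.ceil(hi_x)) + 1, nx)
        sz0, sz1 = max(int(np.floor(lo_z)), 0), min(int(np.ceil(hi_z)) + 1, nz)
        by = yy[sy0:sy1][:, None, None]
        bx = xx[sx0:sx1][None, :, None]
        bz = zz[sz0:sz1][None, None, :]
        if p["kind"] == "sphere":
            r2 = p["radius"] ** 2
            m = (by - cy) ** 2 + (bx - cx) ** 2 + (bz - cz) ** 2 <= r2
        elif p["kind"] == "cylinder":
            r2 = p["radius"] ** 2
            m = ((bx - cx) ** 2 + (bz - cz) ** 2 <= r2) \
                & (np.abs(by - cy) <= p["height"] / 2)
        else:  # box
            sy, sx, sz = p["size"]
            m = (np.abs(by - cy) <= sy / 2) & (np.abs(bx - cx) <= sx / 2) \
                & (np.abs(bz - cz) <= sz / 2)
        view = vol[sy0:sy1, sx0:sx1, sz0:sz1]
        view[m] = p["value"]
    return vol


def random_spheres_spec(shape, n_spheres: int, *, radius_range=(4, 12),
                        value_range=(0.005, 0.02), background: float = 0.0,
                        seed: int = 0, margin: float = 0.1,
                        inscribed: bool = True) -> PhantomSpec:
    """Spheres scattered through the volume, with reproducible placement.

    With ``inscribed=True`` every sphere stays inside the reconstructable
    field of view (a ``margin`` fraction inside the inscribed circle in x-z
    and away from the top/bottom faces) — the right choice when the phantom
    will be reconstructed.  With ``inscribed=False`` spheres are placed
    uniformly over the whole box, so every detector region sees texture;
    use this for registration studies, where featureless overlap strips
    would make the alignment problem ill-posed regardless of method.
    """
    ny, nx, nz = shape
    rng = np.random.default_rng(seed)
    ccx, ccz = (nx - 1) / 2.0, (nz - 1) / 2.0
    rmax_field = min(nx, nz) / 2.0 * (1.0 - margin)
    prims = []
    for _ in range(n_spheres):
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r + 1, ny - r - 2) if ny > 2 * (r + 2) else (ny - 1) / 2.0
        if inscribed:
            rho = rng.uniform(0, max(rmax_field - r, 1.0))
            phi = rng.uniform(0, 2 * np.pi)
            cx, cz = ccx + rho * np.cos(phi), ccz + rho * np.sin(phi)
        else:
            cx = rng.uniform(r + 1, nx - r - 2)
            cz = rng.uniform(r + 1, nz - r - 2)
        prims.append({
            "kind": "sphere",
            "center": (cy, cx, cz),
            "radius": r,
            "value": rng.uniform(*value_range),
        })
    return PhantomSpec(shape=tuple(shape), primitives=tuple(prims),
                       background=background, seed=seed)


# ---------------------------------------------------------------------------
# Forward projection


def forward_project(volume: np.ndarray, geometry: AcquisitionGeometry,
                    axis_x: float | None = None, *, order: int = 3) -> np.ndarray:
    """Parallel-beam line integrals of a (y, x, z) attenuation volume.

    For each angle the object is rotated about the vertical axis located at
    detector abscissa ``axis_x`` (and z = axis_x, so the axis position is
    consistent with the square reconstruction frame), then integrated along
    the beam direction z.  Output stack is (N_theta, n_y, n_x) with unit
    voxel size; the operation is linear in the volume.  ``order`` is the
    spline interpolation order of the rotation (cubic by default; the
    spline prefilter is applied once, not per angle).
    """
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim != 3:
        raise ValueError("volume must be (n_y, n_x, n_z)")
    ny, nx, nz = vol.shape
    if axis_x is None:
        axis_x = (nx - 1) / 2.0
    if not 0 <= axis_x < nx:
        raise ValueError(f"rotation axis {axis_x} outside volume footprint [0, {nx})")
    axis_z = float(axis_x)  # axis at (axis_x, axis_x): matches the square recon frame

    if order > 1:
        vol = ndimage.spline_filter(vol, order=order, mode="constant",
                                    output=np.float32)
    out = np.empty((geometry.n_theta, ny, nx), dtype=np.float64)
    for k, theta in enumerate(geometry.angles_rad):
        c, s = np.cos(theta), np.sin(theta)
        # sample the volume rotated by -theta about (axis_x, axis_z) in the
        # x-z plane: input coords = R(theta) . (output - axis) + axis
        mat = np.array([[1.0, 0.0, 0.0],
                        [0.0, c, -s],
                        [0.0, s, c]])
        center = np.array([0.0, axis_x, axis_z])
        offset = center - mat @ center
        rotated = ndimage.affine_transform(vol, mat, offset=offset, order=order,
                                           mode="constant", cval=0.0,
                                           prefilter=False)
        out[k] = rotated.sum(axis=2)
    return out


# ---------------------------------------------------------------------------
# SOA scan simulation


def default_noise_params() -> dict:
    """Study conditions for the simulated acquisition.

    flat_counts: mean white-field level (detector counts per pixel);
    dark_counts: mean dark level; n_flat / n_dark: frames per tile;
    scale_drift: sigma of the per-tile multiplicative intensity drift;
    jitter_px: bound of the uniform sub-pixel stage jitter per axis;
    flat_gradient: relative amplitude of the smooth flat-field pattern;
    poisson: draw Poisson counting noise; quantize: store uint16 counts.
    """
    return {
        "flat_counts": 5000.0,
        "dark_counts": 100.0,
        "n_flat": 20,
        "n_dark": 10,
        "scale_drift": 0.02,
        "jitter_px": 3.0,
        "flat_gradient": 0.05,
        "poisson": True,
        "quantize": True,
    }


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    true_origins: dict          # TileIndex -> (Y, X) fractional panorama pixels
    nominal_origins: dict       # TileIndex -> (Y, X) commanded
    jitter: dict                # TileIndex -> (dy, dx), true - commanded
    scales: dict                # TileIndex -> intensity scale factor
    center: float               # rotation-axis abscissa, panorama x-coordinate
    jitter_bound: float
    phantom_shape: tuple
    angles_deg: tuple

    def relative_shift(self, a: TileIndex, b: TileIndex) -> tuple:
        """True displacement of tile b's origin relative to tile a's."""
        ya, xa = self.true_origins[a]
        yb, xb = self.true_origins[b]
        return (yb - ya, xb - xa)

    def to_json(self) -> str:
        def keyed(d):
            return {f"{t.iy},{t.ix}": list(np.atleast_1d(v).astype(float)) for t, v in d.items()}

        return json.dumps({
            "true_origins": keyed(self.true_origins),
            "nominal_origins": keyed(self.nominal_origins),
            "jitter": keyed(self.jitter),
            "scales": {f"{t.iy},{t.ix}": float(v) for t, v in self.scales.items()},
            "center": self.center,
            "jitter_bound": self.jitter_bound,
            "phantom_shape": list(self.phantom_shape),
            "angles_deg": list(self.angles_deg),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)

        def unkeyed(d, scalar=False):
            out = {}
            for k, v in d.items():
                iy, ix = k.split(",")
                out[TileIndex(int(iy), int(ix))] = float(v) if scalar else tuple(v)
            return out

        return cls(
            true_origins=unkeyed(raw["true_origins"]),
            nominal_origins=unkeyed(raw["nominal_origins"]),
            jitter=unkeyed(raw["jitter"]),
            scales=unkeyed(raw["scales"], scalar=True),
            center=raw["center"],
            jitter_bound=raw["jitter_bound"],
            phantom_shape=tuple(raw["phantom_shape"]),
            angles_deg=tuple(raw["angles_deg"]),
        )


def _flat_pattern(shape, amplitude, rng) -> np.ndarray:
    """Smooth low-order illumination pattern, distinct per tile."""
    ny, nx = shape
    y = np.linspace(0, np.pi, ny)[:, None]
    x = np.linspace(0, np.pi, nx)[None, :]
    a, b, c = rng.uniform(-1, 1, size=3)
    return 1.0 + amplitude * (a * np.cos(y) + b * np.cos(x) + c * np.sin(y + x) / 2)


def _validate_noise(p: dict) -> dict:
    params = default_noise_params()
    unknown = set(p) - set(params)
    if unknown:
        raise ValueError(f"unknown noise parameter(s): {sorted(unknown)}")
    params.update(p)
    if params["flat_counts"] <= 0 or params["dark_counts"] < 0:
        raise ValueError("flat_counts must be > 0 and dark_counts >= 0")
    if params["n_flat"] < 1 or params["n_dark"] < 1:
        raise ValueError("at least one flat and one dark frame are required")
    if params["scale_drift"] < 0 or params["jitter_px"] < 0 or params["flat_gradient"] < 0:
        raise ValueError("scale_drift, jitter_px and flat_gradient must be >= 0")
    return params


def panorama_projections(phantom: np.ndarray, grid: MosaicGrid,
                         geometry: AcquisitionGeometry,
                         center: float | None = None) -> np.ndarray:
    """Line integrals of the phantom on the full panorama-sized detector.

    The phantom is padded with air up to the grid's panorama footprint (a
    warning reports the uncovered fraction if it is larger instead).  The
    result can be passed to :func:`simulate_soa_scan` as ``projections`` to
    simulate several noise settings of the same scan without re-projecting.
    """
    phantom = np.asarray(phantom, dtype=np.float32)
    h_pan, w_pan = grid.panorama_height, grid.panorama_width
    ny, nx, _ = phantom.shape
    if ny > h_pan or nx > w_pan:
        covered = (min(ny, h_pan) * min(nx, w_pan)) / (ny * nx)
        warnings.warn(
            f"grid footprint ({h_pan} x {w_pan}) does not cover the phantom "
            f"({ny} x {nx}); uncovered fraction {1 - covered:.2f}"
        )
    pad_y = max(h_pan - ny, 0)
    pad_x = max(w_pan - nx, 0)
    if pad_y or pad_x:
        phantom = np.pad(phantom, ((pad_y // 2, pad_y - pad_y // 2),
                                   (pad_x // 2, pad_x - pad_x // 2), (0, 0)))
    if center is None:
        center = (w_pan - 1) / 2.0
    return forward_project(phantom, geometry, axis_x=center)


def simulate_soa_scan(phantom: np.ndarray | None, grid: MosaicGrid,
                      noise_params: dict | None = None, seed: int = 0, *,
                      geometry: AcquisitionGeometry | None = None,
                      center: float | None = None,
                      projections: np.ndarray | None = None,
                      jitter_override: dict | None = None):
    """Simulate a complete sinogram-oriented mosaic acquisition.

    One full 180-degree rotation series is produced per grid position, each
    at one fixed (x, y) offset of the field of view relative to the rotation
    axis; the tile's true offset is the commanded offset plus sub-pixel
    uniform jitter.  Every tile carries its own white/dark frames, intensity
    scale drift and (optionally) Poisson counting noise, stored as 16-bit
    unsigned counts.  All randomness derives from ``seed`` through
    deterministic per-tile substreams.  ``jitter_override`` maps TileIndex
    to an exact (dy, dx) jitter, replacing the random draw — useful for
    controlled alignment studies (tiles not listed get zero jitter).

    Returns ``(tiles, truth)`` with ``tiles`` a ``TileIndex -> TileDataset``
    mapping and ``truth`` the :class:`GroundTruth`.
    """
    params = _validate_noise(noise_params or {})
    if geometry is None:
        geometry = AcquisitionGeometry.uniform(grid.N_theta)
    h_pan, w_pan = grid.panorama_height, grid.panorama_width
    if center is None:
        center = (w_pan - 1) / 2.0

    if projections is None:
        line_integrals = panorama_projections(phantom, grid, geometry, center)
    else:
        line_integrals = np.asarray(projections)
        if line_integrals.shape != (geometry.n_theta, h_pan, w_pan):
            raise ValueError(
                f"projections shape {line_integrals.shape} does not match "
                f"({geometry.n_theta}, {h_pan}, {w_pan})"
            )
    # margin so jittered windows at the mosaic border stay in bounds (air outside)
    margin = int(np.ceil(params["jitter_px"])) + 1
    line_integrals = np.pad(line_integrals,
                            ((0, 0), (margin, margin), (margin, margin)))

    root = np.random.default_rng(seed)
    tile_seeds = root.integers(0, 2**31 - 1, size=grid.n_tiles)

    tiles: dict[TileIndex, TileDataset] = {}
    true_origins, nominal_origins, jitter, scales = {}, {}, {}, {}
    for i, t in enumerate(grid.tiles()):
        rng = np.random.default_rng(tile_seeds[i])
        nom = grid.nominal_origin(t)
        if jitter_override is not None:
            j = np.asarray(jitter_override.get(t, (0.0, 0.0)), dtype=float)
        elif params["jitter_px"] > 0:
            j = rng.uniform(-params["jitter_px"], params["jitter_px"], size=2)
        else:
            j = np.zeros(2)
        true = (nom[0] + j[0], nom[1] + j[1])
        nominal_origins[t], jitter[t], true_origins[t] = nom, tuple(j), true

        y0, x0 = int(np.floor(true[0])), int(np.floor(true[1]))
        fy, fx = true[0] - y0, true[1] - x0
        shifted = apply_fourier_shift(line_integrals, (-fy, -fx), axes=(-2, -1)) \
            if (fy or fx) else line_integrals
        tile_L = shifted[:, margin + y0 : margin + y0 + grid.N_y,
                         margin + x0 : margin + x0 + grid.N_x]
        transmission = np.exp(-tile_L)

        scale = 1.0 + (rng.normal(0, params["scale_drift"])
                       if params["scale_drift"] > 0 else 0.0)
        scales[t] = scale
        flat_img = params["flat_counts"] * _flat_pattern(
            (grid.N_y, grid.N_x), params["flat_gradient"], rng) * scale

        expected = flat_img[None] * transmission + params["dark_counts"]
        white = np.broadcast_to(flat_img + params["dark_counts"],
                                (params["n_flat"], grid.N_y, grid.N_x)).copy()
        dark = np.full((params["n_dark"], grid.N_y, grid.N_x), params["dark_counts"])
        if params["poisson"]:
            data = rng.poisson(expected).astype(np.float64)
            white = rng.poisson(white).astype(np.float64)
            dark = rng.poisson(dark).astype(np.float64)
        else:
            data = expected
        if params["quantize"]:
            data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
            white = np.clip(np.round(white), 0, 65535).astype(np.uint16)
            dark = np.clip(np.round(dark), 0, 65535).astype(np.uint16)

        tiles[t] = TileDataset(
            data=data, data_white=white, data_dark=dark,
            theta=np.asarray(geometry.angles_deg),
            metadata={"tile_index": (t.iy, t.ix), "commanded_position": nom,
                      "exposure_time_s": 0.015, "seed": int(tile_seeds[i])},
        )

    truth = GroundTruth(
        true_origins=true_origins, nominal_origins=nominal_origins, jitter=jitter,
        scales=scales, center=float(center), jitter_bound=params["jitter_px"],
        phantom_shape=tuple(np.asarray(phantom).shape) if phantom is not None
        else (h_pan, w_pan, 0),
        angles_deg=tuple(geometry.angles_deg),
    )
    return tiles, truth
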