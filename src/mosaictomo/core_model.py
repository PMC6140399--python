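"""Shared coordinate conventions, grid manifests, file naming and size accounting.

Conventions used throughout the package
---------------------------------------
* All indices are 0-based and all intervals half-open.
* Image origin is the top-left detector pixel; ``y`` increases downward
  (along the rotation axis), ``x`` increases to the right.
* Projection stacks are ordered ``(theta, y, x)``.
* The object is rotated about the ``y`` axis; the beam travels along ``z``;
  reconstructed slices live in the ``x``--``z`` plane and are square.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MosaicGrid",
    "TileIndex",
    "AcquisitionGeometry",
    "parse_grid_file",
    "serialize_grid_file",
    "tile_filename",
    "total_voxels",
]


@dataclass(frozen=True, order=True)
class TileIndex:
    """Grid position of one tile: row ``iy`` from the top, column ``ix`` from the left."""

    iy: int
    ix: int

    def __post_init__(self) -> None:
        if self.iy < 0 or self.ix < 0:
            raise ValueError(f"tile indices must be non-negative, got ({self.iy}, {self.ix})")


@dataclass(frozen=True)
class MosaicGrid:
    """Layout of an ``n_y`` x ``n_x`` mosaic of detector fields of view.

    Parameters
    ----------
    n_x, n_y :
        Number of fields of view horizontally / vertically.
    N_x, N_y :
        Detector pixels per tile horizontally / vertically.
    N_theta :
        Number of rotation angles acquired per tile scan.
    nominal_overlap_x, nominal_overlap_y :
        Commanded overlap, in pixels, between horizontally / vertically
        adjacent tiles.
    pixel_size :
        Detector pixel size in micrometres (bookkeeping only; geometry is
        expressed in pixels).
    nominal_positions :
        Optional commanded stage coordinates per tile, as read from a grid
        manifest.
    """

    n_x: int
    n_y: int
    N_x: int
    N_y: int
    N_theta: int
    nominal_overlap_x: int = 0
    nominal_overlap_y: int = 0
    pixel_size: float = 1.0
    nominal_positions: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must contain at least one tile in each direction")
        if not (0 <= self.nominal_overlap_x < self.N_x):
            raise ValueError(
                f"nominal_overlap_x={self.nominal_overlap_x} outside [0, N_x={self.N_x})"
            )
        if not (0 <= self.nominal_overlap_y < self.N_y):
            raise ValueError(
                f"nominal_overlap_y={self.nominal_overlap_y} outside [0, N_y={self.N_y})"
            )
        if self.N_theta < 1:
            raise ValueError("N_theta must be >= 1")

    @property
    def n_tiles(self) -> int:
        return self.n_x * self.n_y

    @property
    def step_x(self) -> int:
        """Nominal horizontal pitch between tile origins, in pixels."""
        return self.N_x - self.nominal_overlap_x

    @property
    def step_y(self) -> int:
        """Nominal vertical pitch between tile origins, in pixels."""
        return self.N_y - self.nominal_overlap_y

    @property
    def panorama_width(self) -> int:
        """Width of the stitched panorama at nominal overlaps."""
        return self.n_x * self.N_x - (self.n_x - 1) * self.nominal_overlap_x

    @property
    def panorama_height(self) -> int:
        return self.n_y * self.N_y - (self.n_y - 1) * self.nominal_overlap_y

    def tiles(self) -> list[TileIndex]:
        """Row-major list of all tile indices."""
        return [TileIndex(iy, ix) for iy in range(self.n_y) for ix in range(self.n_x)]

    def nominal_origin(self, idx: TileIndex) -> tuple[float, float]:
        """Commanded (y, x) origin of a tile in panorama pixel coordinates."""
        return (idx.iy * self.step_y, idx.ix * self.step_x)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Parallel-beam rotation geometry: angles in degrees over the half-open [0, 180)."""

    angles_deg: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("angle list must be a non-empty 1-D sequence")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if a[-1] >= 180.0:
            raise ValueError("angles must lie in the half-open interval [0, 180)")
        object.__setattr__(self, "angles_deg", tuple(float(x) for x in a))

    @classmethod
    def uniform(cls, n_theta: int) -> "AcquisitionGeometry":
        """theta_k = k * 180 / N_theta for k = 0..N_theta-1 (0 and 180 deg are redundant)."""
        if n_theta < 1:
            raise ValueError("n_theta must be >= 1")
        return cls(tuple(np.arange(n_theta) * 180.0 / n_theta))

    @property
    def n_theta(self) -> int:
        return len(self.angles_deg)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.angles_deg))


def tile_filename(prefix: str, idx: TileIndex) -> str:
    """Deterministic, sortable tile file name ``{prefix}_y{YY}_x{XX}.h5``.

    The two-digit zero-padded grid indices count from zero; the scheme
    therefore caps at 100 tiles per direction.
    """
    if idx.iy >= 100 or idx.ix >= 100:
        raise ValueError(
            f"two-digit naming scheme supports indices < 100, got ({idx.iy}, {idx.ix})"
        )
    return f"{prefix}_y{idx.iy:02d}_x{idx.ix:02d}.h5"


def total_voxels(grid: MosaicGrid) -> int:
    """Total voxel count of the full reconstruction, ignoring tile overlaps.

    Reconstructed slices are square in the x--z plane, so the volume is
    ``(n_x N_x)^2 * (n_y N_y)`` voxels.
    """
    w = grid.n_x * grid.N_x
    h = grid.n_y * grid.N_y
    return w * w * h


def parse_grid_file(
    manifest: str,
    *,
    N_x: int = 0,
    N_y: int = 0,
    N_theta: int = 1,
    nominal_overlap_x: int = 0,
    nominal_overlap_y: int = 0,
    pixel_size: float = 1.0,
) -> tuple[MosaicGrid, list[TileIndex]]:
    """Parse a grid-position manifest into a :class:`MosaicGrid` and ordered tile list.

    The manifest is plain text, one whitespace-separated record per line::

        iy ix stage_y stage_x

    Lines starting with ``#`` are comments.  The tile set must form a
    complete rectangle; a missing or duplicated (iy, ix) is an error naming
    the offending index.  Commanded stage coordinates are retained as
    ``nominal_positions`` on the returned grid.
    """
    records: dict[TileIndex, tuple[float, float]] = {}
    for lineno, line in enumerate(manifest.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 4:
            raise ValueError(
                f"manifest line {lineno}: expected 'iy ix stage_y stage_x', got {line!r}"
            )
        iy, ix = int(parts[0]), int(parts[1])
        idx = TileIndex(iy, ix)
        if idx in records:
            raise ValueError(f"duplicate tile index ({iy}, {ix}) in manifest")
        records[idx] = (float(parts[2]), float(parts[3]))

    if not records:
        raise ValueError("manifest contains no tile records")

    n_y = max(i.iy for i in records) + 1
    n_x = max(i.ix for i in records) + 1
    for iy in range(n_y):
        for ix in range(n_x):
            if TileIndex(iy, ix) not in records:
                raise ValueError(f"manifest missing tile ({iy}, {ix}) of {n_y}x{n_x} rectangle")

    grid = MosaicGrid(
        n_x=n_x,
        n_y=n_y,
        N_x=N_x or 1,
        N_y=N_y or 1,
        N_theta=N_theta,
        nominal_overlap_x=nominal_overlap_x,
        nominal_overlap_y=nominal_overlap_y,
        pixel_size=pixel_size,
        nominal_positions={k: records[k] for k in sorted(records)},
    )
    return grid, sorted(records)


def serialize_grid_file(grid: MosaicGrid) -> str:
    """Inverse of :func:`parse_grid_file` for valid manifests."""
    out = io.StringIO()
    out.write("# iy ix stage_y stage_x\n")
    for idx in grid.tiles():
        y, x = grid.nominal_positions.get(idx, grid.nominal_origin(idx))
        out.write(f"{idx.iy} {idx.ix} {y:.6g} {x:.6g}\n")
    return out.getvalue()
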