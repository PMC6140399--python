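"""DataExchange-style HDF5 I/O for tile and merged datasets, plus normalization and binning.

Layout (one file per mosaic grid position)::

    /exchange/data        (N_theta, N_y, N_x) raw counts, uint16
    /exchange/data_white  (n_flat, N_y, N_x)
    /exchange/data_dark   (n_dark, N_y, N_x)
    /exchange/theta       (N_theta,) degrees

Merged panoramas reuse the same dialect with /exchange/data stored as
32-bit floats in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .core_model import TileIndex

__all__ = [
    "TileDataset",
    "MergedDataset",
    "write_tile",
    "read_tile",
    "write_merged",
    "read_merged",
    "normalize_projection",
    "downsample_nfold",
]

_EXCHANGE_PATHS = ("exchange/data", "exchange/data_white", "exchange/data_dark")


@dataclass
class TileDataset:
    """One grid position's full rotation series with its flats and darks."""

    data: np.ndarray          # (N_theta, N_y, N_x)
    data_white: np.ndarray    # (n_flat, N_y, N_x)
    data_dark: np.ndarray     # (n_dark, N_y, N_x)
    theta: np.ndarray         # (N_theta,) degrees
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.data_white = np.asarray(self.data_white)
        self.data_dark = np.asarray(self.data_dark)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (N_theta, N_y, N_x)")
        if self.data.shape[0] != self.theta.shape[0]:
            raise ValueError("data.shape[0] must equal len(theta)")
        frame = self.data.shape[1:]
        for name, arr in (("data_white", self.data_white), ("data_dark", self.data_dark)):
            if arr.ndim != 3 or arr.shape[1:] != frame:
                raise ValueError(f"{name} frames must have shape {frame}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def tile_index(self) -> TileIndex | None:
        idx = self.metadata.get("tile_index")
        return TileIndex(*idx) if idx is not None else None

    def normalized(self) -> np.ndarray:
        """Flat/dark corrected transmission stack in [0, 1], float64."""
        flat = np.median(self.data_white, axis=0)
        dark = np.median(self.data_dark, axis=0)
        return normalize_projection(self.data, flat, dark)


@dataclass
class MergedDataset:
    """Stitched projections for all angles, floating point in [0, 1]."""

    data: np.ndarray          # (N_theta, H, W) float32
    theta: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("merged data must be (N_theta, H, W)")
        if self.data.shape[0] != self.theta.shape[0]:
            raise ValueError("merged data.shape[0] must equal len(theta)")


def _write_meta(grp: h5py.Group, metadata: dict) -> None:
    for key, val in metadata.items():
        if isinstance(val, (tuple, list)):
            val = np.asarray(val)
        grp.attrs[key] = val


def _read_meta(grp: h5py.Group) -> dict:
    out = {}
    for key, val in grp.attrs.items():
        if isinstance(val, np.ndarray):
            val = tuple(val.tolist())
        elif isinstance(val, np.generic):
            val = val.item()
        out[key] = val
    return out


def write_tile(path, tile: TileDataset) -> None:
    """Write one tile dataset to a DataExchange-style HDF5 file."""
    with h5py.File(path, "w") as f:
        ex = f.create_group("exchange")
        ex.create_dataset("data", data=tile.data)
        ex.create_dataset("data_white", data=tile.data_white)
        ex.create_dataset("data_dark", data=tile.data_dark)
        ex.create_dataset("theta", data=tile.theta)
        _write_meta(f.create_group("measurement"), tile.metadata)


def read_tile(path, projections=None) -> TileDataset:
    """Read a tile dataset back; losslessly round-trips :func:`write_tile`.

    Parameters
    ----------
    projections :
        Optional index/slice applied to the angle axis, so single
        projections can be read without loading the full series.
    """
    with h5py.File(path, "r") as f:
        for p in _EXCHANGE_PATHS:
            if p not in f:
                raise KeyError(f"not a DataExchange tile file: missing /{p} in {path}")
        sel = slice(None) if projections is None else projections
        data = f["exchange/data"][sel]
        if data.ndim == 2:
            data = data[None]
        theta = np.atleast_1d(f["exchange/theta"][sel]) if "exchange/theta" in f else np.zeros(
            data.shape[0]
        )
        tile = TileDataset(
            data=data,
            data_white=f["exchange/data_white"][()],
            data_dark=f["exchange/data_dark"][()],
            theta=theta,
            metadata=_read_meta(f["measurement"]) if "measurement" in f else {},
        )
    return tile


def write_merged(path, merged: MergedDataset) -> None:
    """Write a stitched panorama stack (float32) in the same HDF5 dialect."""
    with h5py.File(path, "w") as f:
        ex = f.create_group("exchange")
        ex.create_dataset("data", data=merged.data.astype(np.float32))
        ex.create_dataset("theta", data=merged.theta)
        _write_meta(f.create_group("provenance"), merged.provenance)


def read_merged(path) -> MergedDataset:
    with h5py.File(path, "r") as f:
        if "exchange/data" not in f:
            raise KeyError(f"not a DataExchange merged file: missing /exchange/data in {path}")
        return MergedDataset(
            data=f["exchange/data"][()],
            theta=f["exchange/theta"][()],
            provenance=_read_meta(f["provenance"]) if "provenance" in f else {},
        )


def normalize_projection(raw, flat, dark, *, eps: float = 1e-6) -> np.ndarray:
    """Flat-field correction ``(raw - dark) / (flat - dark)`` clipped to [0, 1].

    ``flat`` and ``dark`` may be single frames or (n_frames, N_y, N_x)
    stacks; stacks are reduced over frames by the median (robust against
    zingers).  Pixels where ``flat <= dark`` are guarded by ``eps``.
    """
    raw = np.asarray(raw, dtype=float)
    flat = np.asarray(flat, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if flat.ndim == raw.ndim == 3 and flat.shape[0] != raw.shape[0]:
        flat = np.median(flat, axis=0)
    elif flat.ndim == 3 and raw.ndim == 2:
        flat = np.median(flat, axis=0)
    if dark.ndim == 3 and (raw.ndim == 2 or dark.shape[0] != raw.shape[0]):
        dark = np.median(dark, axis=0)

    denom = flat - dark
    bad = denom <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} pixel(s) with flat <= dark; guarded by eps", stacklevel=2
        )
    denom = np.where(bad, eps, denom)
    return np.clip((raw - dark) / denom, 0.0, 1.0)


def _block_mean(frames: np.ndarray, n: int) -> np.ndarray:
    """n x n block mean over the trailing two axes; trailing remainder truncated."""
    ny, nx = frames.shape[-2:]
    if ny % n or nx % n:
        warnings.warn(
            f"frame shape ({ny}, {nx}) not divisible by {n}; trailing edge truncated",
            stacklevel=3,
        )
    ny, nx = (ny // n) * n, (nx // n) * n
    f = frames[..., :ny, :nx].astype(float)
    f = f.reshape(*frames.shape[:-2], ny // n, n, nx // n, n)
    return f.mean(axis=(-3, -1))


def downsample_nfold(tile: TileDataset, n: int) -> TileDataset:
    """n-fold binning of every projection image by block mean in detector y and x.

    Raw data size per projection shrinks by a factor n^2; the angle axis is
    untouched.  ``n=1`` is the identity.
    """
    if n < 1:
        raise ValueError("binning factor must be >= 1")
    if n == 1:
        return tile
    out_dtype = tile.data.dtype
    data = _block_mean(tile.data, n)
    if np.issubdtype(out_dtype, np.integer):
        data = np.round(data).astype(out_dtype)
    meta = dict(tile.metadata)
    meta["binning"] = int(meta.get("binning", 1)) * n
    return TileDataset(
        data=data,
        data_white=_block_mean(tile.data_white, n),
        data_dark=_block_mean(tile.data_dark, n),
        theta=tile.theta.copy(),
        metadata=meta,
    )
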