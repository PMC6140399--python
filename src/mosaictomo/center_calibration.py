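"""Rotation-center calibration by minimizing reconstruction image entropy.

A slice reconstructed with a mis-set rotation center shows arc/U-shaped
smearing artifacts that widen the grayscale distribution, raising the
Shannon entropy of the image histogram.  Scanning candidate centers and
reconstructing the same sinogram at each therefore yields an entropy curve
with a sharp minimum at the correct center.  One center is calibrated per
mosaic grid row, independently of the other rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CenterTable", "CenterScan", "image_entropy", "scan_center"]


def image_entropy(img: np.ndarray, bins: int = 1024, range=None, mask=None) -> float:
    """Shannon entropy S = -sum p_i ln p_i of the image grayscale histogram.

    ``p_i`` is the fraction of (optionally masked) pixels falling in
    histogram bin ``i``; empty bins contribute zero.  A constant image has
    zero entropy.  If ``range`` does not cover the data, values are clipped
    into it with a warning so every pixel is counted.
    """
    img = np.asarray(img, dtype=float)
    if mask is not None:
        img = img[mask]
    vals = img.ravel()
    if vals.size == 0:
        raise ValueError("cannot compute the entropy of an empty image")
    if bins < 2:
        raise ValueError("at least 2 histogram bins are required")
    if range is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = float(range[0]), float(range[1])
        if vals.min() < lo or vals.max() > hi:
            warnings.warn("histogram range does not cover the data; values clipped")
            vals = np.clip(vals, lo, hi)
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(vals, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / vals.size
    return float(-np.sum(p * np.log(p)))


def _inscribed_circle_mask(shape) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


@dataclass
class CenterScan:
    """Entropy scan of one grid row: candidates, entropies, and the optimum."""

    candidates: np.ndarray
    entropies: np.ndarray
    c_opt: float
    reconstructions: list = field(default_factory=list, repr=False)


@dataclass
class CenterTable:
    """Per-grid-row optimal rotation-center abscissa in panorama x-coordinates."""

    centers: dict = field(default_factory=dict)   # grid row -> c_opt
    scans: dict = field(default_factory=dict)     # grid row -> CenterScan

    def __getitem__(self, row: int) -> float:
        return self.centers[row]

    def to_text(self) -> str:
        """Two columns per line: ``row_index center``."""
        lines = ["# row center"]
        for row in sorted(self.centers):
            lines.append(f"{row} {self.centers[row]:.2f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CenterTable":
        table = cls()
        for line in text.splitlines():
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            row, center = body.split()
            table.centers[int(row)] = float(center)
        return table

    def save(self, path) -> None:
        with open(path, "w") as f:
            f.write(self.to_text())

    @classmethod
    def load(cls, path) -> "CenterTable":
        with open(path) as f:
            return cls.from_text(f.read())


def scan_center(
    sinogram,
    candidates,
    recon=None,
    bins: int = 1024,
    *,
    angles_deg=None,
    mask: bool = True,
    keep_reconstructions: bool = True,
    refine_step: float = 0.0,
) -> CenterScan:
    """Reconstruct a slice at each candidate center and pick the entropy minimum.

    All candidate reconstructions share one histogram range (the global
    min/max over the whole scan) so their entropies are comparable, and the
    histogram is taken over the inscribed circular field of view so
    out-of-field corners do not dominate.  Ties break toward the smallest
    center; the candidate reconstructions are retained on the result for
    manual re-examination.

    Parameters
    ----------
    sinogram :
        ``(N_theta, W)`` stitched sinogram of one slice (a
        :class:`~mosaictomo.reconstruction.SinogramRow` is also accepted).
    candidates :
        Candidate center abscissae, in sinogram column coordinates.
    recon :
        Callable ``recon(data, angles_deg, center) -> 2-D slice``; defaults
        to the built-in filtered backprojection.
    refine_step :
        If > 0, a second scan at this pitch (e.g. 0.25 px) is run over
        +/-1 px around the first argmin.
    """
    data = getattr(sinogram, "data", sinogram)
    data = np.asarray(data, dtype=float)
    if angles_deg is None:
        angles_deg = getattr(sinogram, "angles_deg", None)
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise ValueError("empty candidate list")
    if candidates.min() < 0 or candidates.max() >= data.shape[1]:
        raise ValueError("candidate centers must lie within the sinogram width")

    if recon is None:
        from .reconstruction import fbp_reconstruct_slice

        def recon(d, a, c):
            return fbp_reconstruct_slice(d, angles_deg=a, center=c).image

    def run(cands):
        recons = [np.asarray(recon(data, angles_deg, c), dtype=float) for c in cands]
        lo = min(r.min() for r in recons)
        hi = max(r.max() for r in recons)
        m = _inscribed_circle_mask(recons[0].shape) if mask else None
        ent = np.array([image_entropy(r, bins=bins, range=(lo, hi), mask=m) for r in recons])
        return recons, ent

    recons, entropies = run(candidates)
    best = int(np.argmin(entropies))  # ties: argmin returns the first, i.e. smallest center
    c_opt = float(candidates[best])

    if refine_step > 0:
        fine = np.arange(c_opt - 1.0, c_opt + 1.0 + refine_step / 2, refine_step)
        fine = fine[(fine >= 0) & (fine < data.shape[1])]
        frecons, fent = run(fine)
        candidates = np.concatenate([candidates, fine])
        order = np.argsort(candidates, kind="stable")
        entropies = np.concatenate([entropies, fent])[order]
        recons = [([*recons, *frecons])[i] for i in order]
        candidates = candidates[order]
        c_opt = float(candidates[int(np.argmin(entropies))])

    return CenterScan(
        candidates=candidates,
        entropies=entropies,
        c_opt=c_opt,
        reconstructions=recons if keep_reconstructions else [],
    )
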