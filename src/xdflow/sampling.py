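"""Variable-density radial (VDRad) Cartesian view ordering.

Phase-encode views on the Cartesian (ky, kz) grid are grouped into
center-out, variable-density spokes.  Successive spokes are rotated by the
golden-ratio angle increment (~137.5 deg), which makes any set of
consecutive spokes close to uniformly distributed in angle: masks built
from adjacent spoke groups are complementary, and combining them lowers the
undersampling reduction factor R.

Conventions: grid indices are 0-based with the DC sample at index
``N // 2`` on each axis (FFT-shifted center); this convention is used by
every k-space array in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE_DEG = 360.0 * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # 137.5077640...


def golden_angle(i: int | np.ndarray) -> float | np.ndarray:
    """Angle (degrees, in [0, 360)) of the i-th golden-ratio-ordered spoke.

    Parameters
    ----------
    i : int or array of int
        Spoke index, >= 0.
    """
    i = np.asarray(i)
    if np.any(i < 0):
        raise ValueError("spoke index must be non-negative")
    out = (i * GOLDEN_ANGLE_DEG) % 360.0
    return float(out) if out.ndim == 0 else out


def generate_spoke(
    angle_deg: float,
    grid: tuple[int, int],
    density_exponent: float = 0.0,
) -> np.ndarray:
    """One center-out spoke of on-grid (ky, kz) indices at a given angle.

    The radial step grows with radius as ``(1 + r)**density_exponent`` so
    the sample density along the spoke falls off like ``r**-density_exponent``
    (exponent 0 gives a uniform-density ray).  The radius sequence starts at
    a deterministic sub-step offset derived from the angle, so different
    spokes sample interleaved annuli and their union tiles k-space rather
    than concentrating on shared rings.  The DC index is always the first
    sample; duplicates from rounding are removed, order preserved.

    Returns
    -------
    (n, 2) int array of (ky, kz) indices.
    """
    ny, nz = grid
    if ny < 1 or nz < 1:
        raise ValueError("grid axes must be positive")
    cy, cz = ny // 2, nz // 2
    theta = np.deg2rad(angle_deg)
    dy, dz = np.cos(theta), np.sin(theta)
    rmax = float(np.hypot(max(cy, ny - 1 - cy), max(cz, nz - 1 - cz))) + 1.0

    # per-spoke radial interleave, decorrelated from the angle itself so
    # that angular neighbors sample different annuli
    offset = (angle_deg * 0.6180339887498949) % 1.0
    radii = [0.0]
    r = offset
    while r <= rmax:
        radii.append(r)
        r += (1.0 + r) ** density_exponent if density_exponent > 0 else 1.0
    radii = np.asarray(radii)

    ky = np.rint(cy + radii * dy).astype(int)
    kz = np.rint(cz + radii * dz).astype(int)
    inside = (ky >= 0) & (ky < ny) & (kz >= 0) & (kz < nz)
    pts = np.stack([ky[inside], kz[inside]], axis=1)
    # de-duplicate, keeping first-visit (center-out) order
    _, first = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(first)]


@dataclass
class ViewOrder:
    """Ordered VDRad spokes with their (cardiac bin, echo) mask assignment.

    ``spokes[i]`` is an (n_i, 2) array of (ky, kz) indices acquired
    consecutively; ``mask_assignment[i] = (c, e)`` names the sampling mask
    the spoke belongs to.  ``N_c * N_e`` masks exist.
    """

    grid: tuple[int, int]
    spokes: list = field(default_factory=list)
    mask_assignment: list = field(default_factory=list)
    density_exponent: float = 0.0
    n_cardiac: int = 1
    n_echoes: int = 1

    def mask(self, c: int, e: int) -> np.ndarray:
        """Boolean (Ny, Nz) sampling mask of bin (cardiac c, echo e)."""
        m = np.zeros(self.grid, dtype=bool)
        for spoke, (sc, se) in zip(self.spokes, self.mask_assignment):
            if sc == c and se == e:
                m[spoke[:, 0], spoke[:, 1]] = True
        return m

    def flatten(self) -> np.ndarray:
        """Acquisition-ordered table of (ky, kz, cardiac_bin, echo) rows."""
        rows = []
        for spoke, (c, e) in zip(self.spokes, self.mask_assignment):
            block = np.empty((len(spoke), 4), dtype=int)
            block[:, :2] = spoke
            block[:, 2] = c
            block[:, 3] = e
            rows.append(block)
        return np.concatenate(rows, axis=0)


def build_view_order(
    grid: tuple[int, int],
    n_cardiac: int = 1,
    n_echoes: int = 1,
    spokes_per_mask: int = 8,
    density_exponent: float = 0.0,
) -> ViewOrder:
    """Round-robin golden-angle spokes across the N_c x N_e sampling masks.

    Consecutive spokes go to consecutive masks, so adjacent masks hold
    complementary (golden-angle interleaved) sets of angles.
    """
    n_masks = n_cardiac * n_echoes
    order = ViewOrder(
        grid=tuple(grid),
        density_exponent=density_exponent,
        n_cardiac=n_cardiac,
        n_echoes=n_echoes,
    )
    for i in range(n_masks * spokes_per_mask):
        mask_idx = i % n_masks
        c, e = divmod(mask_idx, n_echoes)
        order.spokes.append(generate_spoke(golden_angle(i), grid, density_exponent))
        order.mask_assignment.append((c, e))
    return order


def reduction_factor(masks: np.ndarray | list, grid: tuple[int, int] | None = None) -> float:
    """Undersampling reduction factor R of one or more masks combined.

    R = (Ny * Nz) / #unique sampled (ky, kz) in the union.  Masks may be
    boolean (Ny, Nz) arrays or (n, 2) index arrays (then ``grid`` is
    required).
    """
    if isinstance(masks, np.ndarray) and masks.ndim == 2 and masks.dtype == bool:
        masks = [masks]
    union = None
    for m in masks:
        m = np.asarray(m)
        if m.dtype == bool:
            g = m.shape
            hit = m
        else:
            if grid is None:
                raise ValueError("grid required for index-array masks")
            g = tuple(grid)
            hit = np.zeros(g, dtype=bool)
            hit[m[:, 0], m[:, 1]] = True
        union = hit if union is None else (union | hit)
    n_sampled = int(union.sum())
    if n_sampled == 0:
        raise ValueError("empty mask union")
    return union.size / n_sampled
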