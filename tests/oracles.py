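"""Independent brute-force oracles for dose statistics.

These deliberately share no code with the library: occupancy comes from an
analytic inside-predicate evaluated on a dense subvoxel lattice, and dose
interpolation is re-implemented here.  They are only feasible on small grids
and serve as ground truth for the fast implementation.
"""

from __future__ import annotations

import numpy as np


def trilinear(values: np.ndarray, idx_xyz: np.ndarray) -> np.ndarray:
    """Plain trilinear interpolation of ``values[k, j, i]`` at (i, j, k)."""
    i, j, k = idx_xyz[:, 0], idx_xyz[:, 1], idx_xyz[:, 2]
    nz, ny, nx = values.shape
    i0 = np.clip(np.floor(i).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(j).astype(int), 0, ny - 2)
    k0 = np.clip(np.floor(k).astype(int), 0, nz - 2)
    fi, fj, fk = i - i0, j - j0, k - k0
    out = np.zeros(len(idx_xyz))
    for dk in (0, 1):
        for dj in (0, 1):
            for di in (0, 1):
                w = (
                    (fi if di else 1 - fi)
                    * (fj if dj else 1 - fj)
                    * (fk if dk else 1 - fk)
                )
                out += w * values[k0 + dk, j0 + dj, i0 + di]
    return out


def brute_force_dose_stats(
    dose_voxels: np.ndarray,
    dose_origin,
    dose_spacing,
    mask_origin,
    mask_spacing,
    mask_shape,
    inside_fn,
    threshold_gy: float,
    supersample: int = 10,
) -> dict:
    """Volume-weighted dose statistics by dense subvoxel enumeration.

    Each voxel of the mask grid is split into ``supersample**3`` subcells;
    a subcell belongs to the region iff ``inside_fn`` holds at its center.
    Dose is interpolated (own trilinear) at each member subcell center.
    """
    dose_origin = np.asarray(dose_origin, float)
    dose_spacing = np.asarray(dose_spacing, float)
    mask_origin = np.asarray(mask_origin, float)
    mask_spacing = np.asarray(mask_spacing, float)
    nz, ny, nx = mask_shape
    s = supersample

    offsets = (np.arange(s) + 0.5) / s - 0.5  # subcell centers within a voxel
    doses, volumes = [], []
    sub_volume_ml = float(np.prod(mask_spacing)) / s**3 / 1000.0
    for k in range(nz):
        zs = mask_origin[2] + (k + offsets) * mask_spacing[2]
        ys = mask_origin[1] + (
            np.repeat(np.arange(ny), s) + np.tile(offsets, ny)
        ) * mask_spacing[1]
        xs = mask_origin[0] + (
            np.repeat(np.arange(nx), s) + np.tile(offsets, nx)
        ) * mask_spacing[0]
        ZZ, YY, XX = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.column_stack([XX.ravel(), YY.ravel(), ZZ.ravel()])
        member = inside_fn(pts)
        if not member.any():
            continue
        pts = pts[member]
        idx = (pts - dose_origin) / dose_spacing
        doses.append(trilinear(dose_voxels, idx))
        volumes.append(np.full(member.sum(), sub_volume_ml))

    d = np.concatenate(doses)
    v = np.concatenate(volumes)
    order = np.argsort(d)
    d_sorted, v_sorted = d[order], v[order]
    cum = np.cumsum(v_sorted)
    median = float(np.interp(0.5 * cum[-1], cum - 0.5 * v_sorted, d_sorted))
    return {
        "min_gy": float(d.min()),
        "max_gy": float(d.max()),
        "median_gy": median,
        "vol_in_isodose_ml": float(v[d >= threshold_gy].sum()),
        "total_volume_ml": float(v.sum()),
    }
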