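"""Compiled inner loops for the radial-gradient-convergence (RGC) sums.

The RGC at an output pixel c is the ring-weighted average, over neighboring
gradient samples p within distance 2R, of how well the intensity gradient at
p points at c:

    RGC(c) = sum_i w(d_i) D_i / sum_i w(d_i),
    D_i = max(0, 1 - dperp_i / d_i)   if grad(p_i) . (c - p_i) > 0
         = 0                          otherwise or when |grad| < eps,

where dperp is the perpendicular distance from c to the line through p_i in
the gradient direction.  The weight w is a ring (zero at the center: a pixel
cannot vote for itself), peaked near the PSF flank:

    w(d) = [(d / sigma_w) exp(-d^2 / (2 sigma_w^2))]^P,  sigma_w = R / 2.355,

truncated at d = 2R.  Distances are in raw-pixel units; in 3D an anisotropic
metric d^2 = dx^2 + dy^2 + (dz/rho)^2 accounts for the axially elongated PSF
(all 3D geometry below is done in the rho-scaled space, where the metric is
Euclidean again).

The kernels iterate offsets outermost so the gradient reads are sequential;
borders are handled by mirror reflection of indices.  Both kernels accept an
output region of interest so large time series can be reconstructed only
where a measurement needs them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "ring_weight",
    "build_offsets_2d",
    "build_offsets_3d",
    "rgc_kernel_2d",
    "rgc_kernel_3d",
]

# minimum center-to-neighbor distance, in magnified pixels, below which the
# dperp/d ratio is numerically singular and the neighbor is excluded
MIN_NEIGHBOR_DIST_MAG = 0.1


def ring_weight(d: np.ndarray, radius: float, exponent: int = 4) -> np.ndarray:
    """Ring-shaped radius weighting w(d); d and radius in raw pixels.

    R is interpreted as the FWHM of the ring, sigma_w = R / 2.355; the
    weight vanishes at d = 0 and is truncated beyond d = 2R.
    """
    d = np.asarray(d, dtype=np.float64)
    sigma_w = radius / 2.355
    base = (d / sigma_w) * np.exp(-(d ** 2) / (2.0 * sigma_w ** 2))
    w = base ** exponent
    return np.where(d <= 2.0 * radius, w, 0.0)


def build_offsets_2d(radius: float, magnification: int, exponent: int = 4,
                     rel_weight_min: float = 0.0):
    """Neighbor offset table for the 2D RGC sum.

    Returns integer offsets (di, dj) on the magnified grid, the unit
    direction from neighbor to center, and the ring weight, for all offsets
    with MIN_NEIGHBOR_DIST_MAG <= |offset| and distance <= 2R raw pixels.
    ``rel_weight_min`` optionally drops offsets whose ring weight is below
    that fraction of the maximum (a numerical truncation like a Gaussian
    filter's support cutoff; 0 keeps the full 2R neighborhood).
    """
    m = int(magnification)
    reach = int(np.ceil(2.0 * radius * m))
    di, dj = np.mgrid[-reach: reach + 1, -reach: reach + 1]
    di = di.ravel()
    dj = dj.ravel()
    d_mag = np.hypot(di, dj)
    d = d_mag / m  # raw-pixel units
    keep = (d_mag >= MIN_NEIGHBOR_DIST_MAG) & (d <= 2.0 * radius)
    di, dj, d, d_mag = di[keep], dj[keep], d[keep], d_mag[keep]
    w = ring_weight(d, radius, exponent)
    if rel_weight_min > 0.0:
        sel = w >= rel_weight_min * w.max()
        di, dj, d, d_mag, w = di[sel], dj[sel], d[sel], d_mag[sel], w[sel]
    # unit vector from neighbor p to center c: (c - p) = (-di, -dj)
    uy = -di / d_mag
    ux = -dj / d_mag
    off_int = np.stack([di, dj], axis=1).astype(np.int64)
    off_f = np.stack([uy, ux, w], axis=1)
    return off_int, off_f


def build_offsets_3d(
    radius: float,
    magnification: int,
    zstep_px: float,
    rho: float,
    exponent: int = 4,
    rel_weight_min: float = 0.0,
    max_reach_z: int | None = None,
):
    """Neighbor offset table for the 3D RGC sum.

    ``zstep_px`` is the axial voxel pitch of the magnified grid expressed in
    raw lateral pixels (= (dz / Mz) / pixel_size).  The anisotropic metric
    divides axial displacements by rho, so the axial reach is 2 R rho;
    ``max_reach_z`` caps it (mirror-reflected indices beyond the volume
    height only re-sample voxels already in the neighborhood).
    """
    m = int(magnification)
    reach_l = int(np.ceil(2.0 * radius * m))
    reach_z = int(np.ceil(2.0 * radius * rho / zstep_px))
    if max_reach_z is not None:
        reach_z = min(reach_z, int(max_reach_z))
    dk, di, dj = np.mgrid[-reach_z: reach_z + 1, -reach_l: reach_l + 1, -reach_l: reach_l + 1]
    dk = dk.ravel()
    di = di.ravel()
    dj = dj.ravel()
    # displacement from center c to neighbor p in rho-scaled raw-pixel coords
    vz = dk * zstep_px / rho
    vy = di / m
    vx = dj / m
    d = np.sqrt(vz * vz + vy * vy + vx * vx)
    keep = (d * m >= MIN_NEIGHBOR_DIST_MAG) & (d <= 2.0 * radius)
    dk, di, dj, d = dk[keep], di[keep], dj[keep], d[keep]
    vz, vy, vx = vz[keep], vy[keep], vx[keep]
    w = ring_weight(d, radius, exponent)
    if rel_weight_min > 0.0:
        sel = w >= rel_weight_min * w.max()
        dk, di, dj, d, w = dk[sel], di[sel], dj[sel], d[sel], w[sel]
        vz, vy, vx = vz[sel], vy[sel], vx[sel]
    off_int = np.stack([dk, di, dj], axis=1).astype(np.int64)
    # unit vector from neighbor to center = -(v)/|v|
    off_f = np.stack([-vz / d, -vy / d, -vx / d, w], axis=1)
    return off_int, off_f


@njit(cache=False)
def rgc_kernel_2d(g, off_int, off_f, i0, i1, j0, j1, eps2):  # pragma: no cover - compiled
    """Weighted-average convergence sum on a 2D magnified grid.

    g : (H, W, 2) gradient field, components (gy, gx).
    off_int : (n, 2) integer offsets (di, dj).
    off_f : (n, 3) per-offset (uy, ux, w).
    i0..j1 : output region of interest (half-open) in magnified pixels.
    eps2 : squared gradient-magnitude floor; weaker gradients do not vote.

    Returns num/den of the RGC sum for the ROI (before the sensitivity
    power and intensity weighting).
    """
    H, W = g.shape[0], g.shape[1]
    ny, nx = i1 - i0, j1 - j0
    num = np.zeros((ny, nx))
    wsum = 0.0
    noff = off_int.shape[0]
    for q in range(noff):
        wsum += off_f[q, 2]
    for q in range(noff):
        di = off_int[q, 0]
        dj = off_int[q, 1]
        uy = off_f[q, 0]
        ux = off_f[q, 1]
        w = off_f[q, 2]
        for ii in range(ny):
            i = i0 + ii + di
            if i < 0:
                i = -i
            elif i >= H:
                i = 2 * H - 2 - i
            jb = j0 + dj
            for jj in range(nx):
                j = jb + jj
                if j < 0:
                    j = -j
                elif j >= W:
                    j = 2 * W - 2 - j
                ay = g[i, j, 0]
                ax = g[i, j, 1]
                gg = ax * ax + ay * ay
                if gg < eps2 or gg == 0.0:
                    continue
                if ax * ux + ay * uy <= 0.0:
                    continue
                cross = ax * uy - ay * ux
                D = 1.0 - np.sqrt(cross * cross / gg)
                if D > 0.0:
                    num[ii, jj] += w * D
    return num / wsum


@njit(cache=False)
def rgc_kernel_3d(g, off_int, off_f, k0, k1, i0, i1, j0, j1, eps2):  # pragma: no cover - compiled
    """Weighted-average convergence sum on a 3D magnified grid.

    g : (Z, H, W, 3) gradient field in rho-scaled space, components
        (gz, gy, gx), all in intensity per raw lateral pixel.
    off_int : (n, 3) integer offsets (dk, di, dj).
    off_f : (n, 4) per-offset (uz, uy, ux, w) with u the scaled-space unit
        vector from neighbor to center.
    """
    Z, H, W = g.shape[0], g.shape[1], g.shape[2]
    nz, ny, nx = k1 - k0, i1 - i0, j1 - j0
    num = np.zeros((nz, ny, nx))
    wsum = 0.0
    noff = off_int.shape[0]
    for q in range(noff):
        wsum += off_f[q, 3]
    for q in range(noff):
        dk = off_int[q, 0]
        di = off_int[q, 1]
        dj = off_int[q, 2]
        uz = off_f[q, 0]
        uy = off_f[q, 1]
        ux = off_f[q, 2]
        w = off_f[q, 3]
        for kk in range(nz):
            k = k0 + kk + dk
            if k < 0:
                k = -k
            elif k >= Z:
                k = 2 * Z - 2 - k
            if k < 0:  # very thin stacks with long axial reach: clamp
                k = 0
            elif k >= Z:
                k = Z - 1
            for ii in range(ny):
                i = i0 + ii + di
                if i < 0:
                    i = -i
                elif i >= H:
                    i = 2 * H - 2 - i
                jb = j0 + dj
                for jj in range(nx):
                    j = jb + jj
                    if j < 0:
                        j = -j
                    elif j >= W:
                        j = 2 * W - 2 - j
                    az = g[k, i, j, 0]
                    ay = g[k, i, j, 1]
                    ax = g[k, i, j, 2]
                    gg = ax * ax + ay * ay + az * az
                    if gg < eps2 or gg == 0.0:
                        continue
                    if ax * ux + ay * uy + az * uz <= 0.0:
                        continue
                    cx = ay * uz - az * uy
                    cy = az * ux - ax * uz
                    cz = ax * uy - ay * ux
                    D = 1.0 - np.sqrt((cx * cx + cy * cy + cz * cz) / gg)
                    if D > 0.0:
                        num[kk, ii, jj] += w * D
    return num / wsum
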