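"""Volumetric reconstruction: multiplane registration and 3D RGC.

Multifocal acquisitions image several focal planes simultaneously; after a
bead-calibrated lateral registration the planes form a volume, which is
band-limited interpolated in 3D (mirror-extended axially: nine planes are
few) and transformed by the 3D radial gradient convergence.  The
convergence neighborhood uses the anisotropic distance
d^2 = dx^2 + dy^2 + (dz_/rho)^2 so the axially elongated PSF contributes
votes over its full axial extent; all geometry is evaluated in the
rho-scaled space where that metric is Euclidean.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional, Tuple

import numpy as np

from ._kernels import build_offsets_3d, rgc_kernel_3d
from .errors import InvalidInputError, InvalidParameterError, LowConfidenceError
from .interpolation import fourier_interpolate_volume, fourier_shift
from .rgc import GRADIENT_EPS_REL
from .temporal import temporal_project
from .types import PlaneRegistration, Settings3D, SRVolume, VolumeStack

__all__ = ["register_planes", "apply_registration", "rgc_volume", "reconstruct3d"]


def _phase_correlation(reference: np.ndarray, moving: np.ndarray,
                       band_limit: float = 0.5):
    """Phase-correlation surface; peaks at the shift of ``moving`` vs reference.

    The cross spectrum is whitened (phase-only) but band-limited to
    ``band_limit`` of Nyquist before the inverse transform: diffraction-
    limited images carry no structure near Nyquist, and whitening would
    otherwise let the noise there dilute the correlation peak.
    """
    f_ref = np.fft.fft2(reference)
    f_mov = np.fft.fft2(moving)
    cross = f_mov * np.conj(f_ref)  # peak at the shift of `moving` vs reference
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    h, w = reference.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    keep = np.hypot(fy, fx) <= band_limit * 0.5
    corr = np.fft.ifft2(np.where(keep, cross / mag, 0.0)).real
    return corr


def _quadratic_refine(c_m: float, c_0: float, c_p: float) -> float:
    """Subpixel offset of a peak from three samples by quadratic fit."""
    denom = c_m - 2.0 * c_0 + c_p
    if denom == 0:
        return 0.0
    delta = 0.5 * (c_m - c_p) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _peak_shift(corr: np.ndarray, contrast_min: float) -> Tuple[float, float]:
    h, w = corr.shape
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    peak_val = corr[peak]
    # background: upper envelope (99th pct) of |corr| away from a 5x5 peak
    # neighborhood; an unmatched (featureless) plane peaks barely above it
    mask = np.ones_like(corr, dtype=bool)
    yy = (np.arange(-2, 3) + peak[0]) % h
    xx = (np.arange(-2, 3) + peak[1]) % w
    mask[np.ix_(yy, xx)] = False
    background = float(np.percentile(np.abs(corr[mask]), 99.0))
    if background <= 0 or peak_val < contrast_min * background:
        raise LowConfidenceError(
            f"correlation peak contrast {peak_val / max(background, 1e-30):.1f} "
            f"below {contrast_min}; plane lacks registerable features"
        )
    py, px = peak
    dy = _quadratic_refine(corr[(py - 1) % h, px], peak_val, corr[(py + 1) % h, px])
    dx = _quadratic_refine(corr[py, (px - 1) % w], peak_val, corr[py, (px + 1) % w])
    sy = py + dy
    sx = px + dx
    if sy > h / 2:
        sy -= h
    if sx > w / 2:
        sx -= w
    return sy, sx


def register_planes(
    bead_stack: np.ndarray,
    reference_plane: Optional[int] = None,
    contrast_min: float = 3.0,
) -> PlaneRegistration:
    """Per-plane lateral shifts of a bead calibration stack (Z x H x W).

    Each plane is phase-correlated against the central (or chosen
    reference) plane; the correlation peak is refined to subpixel by a
    3-point quadratic fit per axis.  A plane whose peak does not stand at
    least ``contrast_min`` times above the background raises a
    low-confidence error.  The residual error reported is the mean
    remaining shift after applying the registration.
    """
    beads = np.asarray(bead_stack, dtype=np.float64)
    if beads.ndim != 3:
        raise InvalidInputError("bead stack must be Z x H x W")
    z, h, w = beads.shape
    if reference_plane is None:
        reference_plane = z // 2
    ref = beads[reference_plane]
    shifts = np.zeros((z, 2))
    for p in range(z):
        if p == reference_plane:
            continue
        corr = _phase_correlation(ref, beads[p])
        shifts[p] = _peak_shift(corr, contrast_min)
    for p in range(z):
        if abs(shifts[p, 0]) >= h / 4 or abs(shifts[p, 1]) >= w / 4:
            raise LowConfidenceError(
                f"plane {p} shift {tuple(shifts[p])} exceeds a quarter field"
            )
    reg = PlaneRegistration(shifts=shifts, reference_plane=reference_plane)
    aligned = apply_registration(beads, reg)
    residuals = []
    for p in range(z):
        if p == reference_plane:
            continue
        corr = _phase_correlation(ref, aligned[p])
        ry, rx = _peak_shift(corr, 1.0)  # contrast already established
        residuals.append(np.hypot(ry, rx))
    reg.residual_error = float(np.mean(residuals)) if residuals else 0.0
    return reg


def apply_registration(volume_frame: np.ndarray, reg: PlaneRegistration) -> np.ndarray:
    """Align each plane of a Z x H x W frame by its registered shift.

    Translation is band-limited (Fourier phase ramp), conserving the
    per-plane intensity sum; integer shifts relocate pixels exactly.
    """
    vol = np.asarray(volume_frame, dtype=np.float64)
    if vol.ndim != 3:
        raise InvalidInputError("volume frame must be Z x H x W")
    if vol.shape[0] != reg.n_planes:
        raise InvalidInputError(
            f"registration covers {reg.n_planes} planes, frame has {vol.shape[0]}"
        )
    out = np.empty_like(vol)
    for p in range(vol.shape[0]):
        dy, dx = reg.shifts[p]
        out[p] = fourier_shift(vol[p], (-dy, -dx))
        if reg.intensity_scale is not None:
            out[p] *= reg.intensity_scale[p]
    return out


@lru_cache(maxsize=16)
def _offsets_3d(radius: float, magnification: int, zstep_px: float, rho: float,
                exponent: int, rel_weight_min: float, max_reach_z: int):
    return build_offsets_3d(radius, magnification, zstep_px, rho, exponent,
                            rel_weight_min, max_reach_z)


def rgc_volume(
    volume: np.ndarray,
    settings: Settings3D,
    pixel_size: float,
    dz: float,
    mz: int,
    roi: Optional[Tuple[int, int, int, int, int, int]] = None,
    rel_weight_min: float = 0.0,
) -> np.ndarray:
    """3D RGC map of one Z x H x W frame on the (Mz Z) x (M H) x (M W) grid."""
    m = settings.magnification
    mag = fourier_interpolate_volume(volume, m, mz)
    zm, hm, wm = mag.shape
    if zm < 3:
        raise InvalidParameterError(
            f"axial neighborhood needs >= 3 magnified voxels, got {zm}"
        )
    if roi is None:
        roi = (0, zm, 0, hm, 0, wm)
    k0, k1, i0, i1, j0, j1 = roi
    if not (0 <= k0 < k1 <= zm and 0 <= i0 < i1 <= hm and 0 <= j0 < j1 <= wm):
        raise InvalidParameterError(f"roi {roi} outside the {zm}x{hm}x{wm} volume")
    padded = np.pad(mag, 1, mode="reflect")
    gz = 0.5 * (padded[2:, 1:-1, 1:-1] - padded[:-2, 1:-1, 1:-1])
    gy = 0.5 * (padded[1:-1, 2:, 1:-1] - padded[1:-1, :-2, 1:-1])
    gx = 0.5 * (padded[1:-1, 1:-1, 2:] - padded[1:-1, 1:-1, :-2])
    # express all components per raw lateral pixel, then scale z by rho
    zstep_px = (dz / mz) / pixel_size
    gz = gz * (settings.rho / zstep_px)
    gy = gy * m
    gx = gx * m
    g = np.ascontiguousarray(np.stack([gz, gy, gx], axis=-1))
    gmax2 = float(np.max(gz ** 2 + gy ** 2 + gx ** 2))
    eps2 = (GRADIENT_EPS_REL ** 2) * gmax2
    off_int, off_f = _offsets_3d(
        float(settings.radius), int(m), float(zstep_px), float(settings.rho),
        int(settings.weight_exponent), float(rel_weight_min), zm - 1,
    )
    conv = rgc_kernel_3d(g, off_int, off_f, k0, k1, i0, i1, j0, j1, eps2)
    out = np.clip(conv, 0.0, None) ** settings.sensitivity
    if settings.intensity_weighting:
        out = out * np.clip(mag[k0:k1, i0:i1, j0:j1], 0.0, None)
    return out


def reconstruct3d(
    volumes: VolumeStack,
    settings: Optional[Settings3D] = None,
    registration: Optional[PlaneRegistration] = None,
    roi: Optional[Tuple[int, int, int, int, int, int]] = None,
    rel_weight_min: float = 0.0,
) -> SRVolume:
    """Full volumetric pipeline: 3D interpolation, 3D RGC, temporal compression.

    ``roi`` restricts the reconstructed output region (z0, z1, y0, y1,
    x0, x1) in magnified voxels, which keeps long time series affordable
    when only part of the volume is measured.  ``rel_weight_min`` drops
    convergence neighbors whose ring weight is below that fraction of the
    maximum (numerical support truncation; 0 = the exact 2R neighborhood).
    """
    if settings is None:
        settings = Settings3D()
    mz = settings.resolve_axial_magnification(volumes.dz, volumes.pixel_size)
    if volumes.n_planes * mz < 3:
        raise InvalidParameterError("axial neighborhood smaller than 3 voxels")
    maps = []
    for t in range(volumes.n_frames):
        frame = volumes.frames[t]
        if registration is not None:
            frame = np.clip(apply_registration(frame, registration), 0.0, None)
        maps.append(rgc_volume(frame, settings, volumes.pixel_size, volumes.dz,
                               mz, roi=roi, rel_weight_min=rel_weight_min))
    stack = np.stack(maps)
    voxels = temporal_project(stack, settings.temporal_mode)
    return SRVolume(
        voxels=voxels,
        pixel_size_out=volumes.pixel_size / settings.magnification,
        voxel_size_z=volumes.dz / mz,
        window=(0, volumes.n_frames - 1),
        settings=settings,
        roi=roi,
    )
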