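"""2D radial gradient convergence: interpolation -> gradients -> RGC maps.

Each raw frame is band-limited interpolated onto the magnified grid,
centered-difference gradients are computed there (interpolation strictly
before gradients; spectral derivatives would amplify ringing), and the RGC
transform turns the gradient field into a map that peaks where gradients
converge radially - i.e. at emitter positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np

from ._kernels import build_offsets_2d, rgc_kernel_2d
from .errors import InvalidInputError, InvalidParameterError
from .interpolation import fourier_interpolate
from .types import ImageStack, ReconstructionSettings, RGCStack

__all__ = ["GradientField", "spatial_gradients", "rgc_frame", "rgc_stack"]

# relative gradient-magnitude floor: weaker gradients are noise votes
GRADIENT_EPS_REL = 1e-6


@dataclass
class GradientField:
    """Centered-difference intensity gradients on the magnified grid."""

    gy: np.ndarray  # d(intensity)/d(row), per magnified pixel
    gx: np.ndarray  # d(intensity)/d(col), per magnified pixel

    def __post_init__(self) -> None:
        if self.gy.shape != self.gx.shape:
            raise InvalidInputError("gradient components must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gy, self.gx)


def spatial_gradients(mag_frame: np.ndarray) -> GradientField:
    """Centered finite-difference gradients, borders by reflection padding."""
    arr = np.asarray(mag_frame, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError("expected a 2-D magnified frame")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("magnified frame contains non-finite values")
    padded = np.pad(arr, 1, mode="reflect")
    gy = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
    gx = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
    return GradientField(gy=gy, gx=gx)


@lru_cache(maxsize=32)
def _offsets_2d(radius: float, magnification: int, exponent: int):
    return build_offsets_2d(radius, magnification, exponent)


def rgc_frame(
    mag_frame: np.ndarray,
    grads: GradientField,
    settings: ReconstructionSettings,
    pixel_size: Optional[float] = None,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> np.ndarray:
    """Radial gradient convergence map of one magnified frame.

    Parameters
    ----------
    mag_frame : ndarray
        Interpolated frame on the magnified grid (used for the optional
        intensity weighting).
    grads : GradientField
        Gradients of ``mag_frame``.
    settings : ReconstructionSettings
        Radius, sensitivity, magnification, weighting options.
    pixel_size : float, optional
        Raw pixel pitch in nm; kept for interface symmetry with the 3D
        transform (2D geometry only needs relative distances).
    roi : (i0, i1, j0, j1), optional
        Half-open output window in magnified pixels; default full frame.

    Returns
    -------
    ndarray
        Non-negative RGC map, ``(sum w D / sum w)^S``; zero wherever the
        frame is spatially constant.
    """
    if grads.gy.shape != mag_frame.shape:
        raise InvalidInputError("gradients do not match the magnified frame")
    if settings.radius * settings.magnification < 1:
        raise InvalidParameterError("radius * magnification must be >= 1")
    h, w = mag_frame.shape
    if roi is None:
        roi = (0, h, 0, w)
    i0, i1, j0, j1 = roi
    if not (0 <= i0 < i1 <= h and 0 <= j0 < j1 <= w):
        raise InvalidParameterError(f"roi {roi} outside the {h}x{w} frame")
    off_int, off_f = _offsets_2d(
        float(settings.radius), int(settings.magnification), int(settings.weight_exponent)
    )
    g = np.ascontiguousarray(np.stack([grads.gy, grads.gx], axis=-1))
    gmax2 = float(np.max(grads.gy ** 2 + grads.gx ** 2))
    eps2 = (GRADIENT_EPS_REL ** 2) * gmax2
    conv = rgc_kernel_2d(g, off_int, off_f, i0, i1, j0, j1, eps2)
    out = np.clip(conv, 0.0, None) ** settings.sensitivity
    if settings.intensity_weighting:
        out = out * np.clip(mag_frame[i0:i1, j0:j1], 0.0, None)
    return out


def rgc_stack(
    stack: ImageStack,
    settings: ReconstructionSettings,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> RGCStack:
    """Apply interpolate -> gradients -> RGC to every frame of a stack.

    Frames are processed independently, so the result does not depend on
    the processing order.
    """
    m = settings.magnification
    maps = []
    for t in range(stack.n_frames):
        try:
            mag = fourier_interpolate(stack.frames[t], m)
            grads = spatial_gradients(mag)
            maps.append(rgc_frame(mag, grads, settings, stack.pixel_size, roi=roi))
        except (InvalidInputError, InvalidParameterError) as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
    return RGCStack(
        maps=np.stack(maps),
        settings=settings,
        pixel_size_out=stack.pixel_size / m,
        frame_interval=stack.frame_interval,
    )
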