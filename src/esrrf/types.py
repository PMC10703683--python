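"""Domain containers for raw data, reconstruction settings and results.

Conventions used throughout the package
---------------------------------------
* Raw frames are ``T x H x W`` (time, rows, columns) non-negative floats;
  volumetric data adds a plane axis, ``T x Z x H x W``.
* ``pixel_size`` is the raw lateral pixel pitch in nanometres;
  ``frame_interval`` is seconds per frame; ``dz`` is the axial plane
  spacing in nanometres.
* Magnified grids are sample-aligned with the raw grid: magnified pixel
  ``j`` sits at raw-pixel coordinate ``j / M``, so ``out[::M]`` of a
  magnified image falls exactly on the raw samples.
* The radius ``R`` is expressed in *raw* pixels; the sensitivity ``S`` is
  the exponent applied to the weighted radial-gradient-convergence sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)


class TemporalMode(str, Enum):
    """Temporal compression of the RGC stack into one super-resolved image.

    AVG  - per-pixel temporal mean,
    VAR  - per-pixel population variance,
    TAC2 - lag-1 second-order auto-cumulant (mean-subtracted lag product),
           negative values clamped to zero.
    """

    AVG = "AVG"
    VAR = "VAR"
    TAC2 = "TAC2"


def _as_frames(frames: np.ndarray, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim != ndim:
        raise InvalidInputError(f"{name} must be {ndim}-dimensional, got {arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise InvalidInputError(f"{name} contains negative intensities")
    return arr


@dataclass
class ImageStack:
    """A raw time series of diffraction-limited frames (T x H x W)."""

    frames: np.ndarray
    pixel_size: float  # nm per raw pixel
    frame_interval: float = 0.01  # s

    def __post_init__(self) -> None:
        self.frames = _as_frames(self.frames, 3, "frames")
        t, h, w = self.frames.shape
        if t < 1:
            raise InvalidInputError("need at least one frame")
        if h < 8 or w < 8:
            raise InvalidInputError(f"frames must be at least 8x8, got {h}x{w}")
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise InvalidParameterError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def mean_image(self) -> np.ndarray:
        """Temporal mean: the diffraction-limited (wide-field) equivalent."""
        return self.frames.mean(axis=0)


@dataclass
class VolumeStack:
    """A raw multiplane time series (T x Z x H x W), e.g. from MFM."""

    frames: np.ndarray
    pixel_size: float  # nm, lateral
    dz: float  # nm between consecutive focal planes
    frame_interval: float = 0.02  # s

    def __post_init__(self) -> None:
        self.frames = _as_frames(self.frames, 4, "frames")
        t, z, h, w = self.frames.shape
        if z < 2:
            raise InvalidInputError("volume stacks need at least 2 planes")
        if h < 8 or w < 8:
            raise InvalidInputError(f"planes must be at least 8x8, got {h}x{w}")
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel_size must be > 0")
        if not (self.dz > 0):
            raise InvalidParameterError("dz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_planes(self) -> int:
        return self.frames.shape[1]


@dataclass
class ReconstructionSettings:
    """Parameters of the 2D radial-gradient-convergence reconstruction.

    magnification
        Integer grid refinement M (magnified pixel = pixel_size / M).
    radius
        R, spatial extent of the weighting ring in raw pixels; should match
        the PSF extent.
    sensitivity
        S >= 1, exponent sharpening the convergence map.
    temporal_mode
        How the per-frame RGC maps are compressed in time.
    intensity_weighting
        Multiply the RGC map by the interpolated intensity.
    weight_exponent
        Exponent of the ring-shaped radial weighting function.
    """

    magnification: int = 4
    radius: float = 1.5
    sensitivity: float = 4.0
    temporal_mode: TemporalMode = TemporalMode.VAR
    intensity_weighting: bool = False
    weight_exponent: int = 4

    def __post_init__(self) -> None:
        self.temporal_mode = TemporalMode(self.temporal_mode)
        if not (isinstance(self.magnification, (int, np.integer)) and self.magnification >= 1):
            raise InvalidParameterError("magnification must be an integer >= 1")
        if self.magnification > 10:
            raise InvalidParameterError("magnification must be <= 10")
        if not (self.radius > 0):
            raise InvalidParameterError("radius must be > 0")
        if self.radius * self.magnification < 1:
            raise InvalidParameterError(
                "radius * magnification must be >= 1 so the neighborhood spans "
                "at least one magnified pixel"
            )
        if not (self.sensitivity >= 1):
            raise InvalidParameterError("sensitivity must be >= 1")
        if not (isinstance(self.weight_exponent, (int, np.integer)) and self.weight_exponent >= 1):
            raise InvalidParameterError("weight_exponent must be an integer >= 1")

    @property
    def edge_border(self) -> int:
        """Width (magnified px) of the border flagged as edge-affected."""
        return int(math.ceil(2 * self.radius * self.magnification))


@dataclass
class Settings3D(ReconstructionSettings):
    """3D reconstruction settings: adds axial magnification and PSF anisotropy.

    axial_magnification
        Mz; axial voxel of the output = dz / Mz. ``None`` selects
        round(dz / (pixel_size / M)) capped at 8 when the reconstruction is
        invoked (near-isotropic voxels, bounded memory).
    rho
        Axial / lateral PSF elongation ratio (>= 1). The convergence
        neighborhood uses the anisotropic distance
        d^2 = dx^2 + dy^2 + (dz_/rho)^2, extending the axial reach of the
        ring weighting by rho.
    """

    axial_magnification: Optional[int] = None
    rho: float = 2.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.axial_magnification is not None:
            if not (isinstance(self.axial_magnification, (int, np.integer)) and self.axial_magnification >= 1):
                raise InvalidParameterError("axial_magnification must be an integer >= 1")
        if not (self.rho >= 1):
            raise InvalidParameterError("rho must be >= 1")

    def resolve_axial_magnification(self, dz: float, pixel_size: float) -> int:
        """Concrete Mz for a given geometry; warns when voxels are anisotropic."""
        if self.axial_magnification is None:
            mz = int(round(dz / (pixel_size / self.magnification)))
            mz = max(1, min(mz, 8))
        else:
            mz = int(self.axial_magnification)
        lateral = pixel_size / self.magnification
        axial = dz / mz
        if not (0.5 <= axial / lateral <= 2.0):
            logger.warning(
                "anisotropic output voxels: axial %.1f nm vs lateral %.1f nm "
                "(Mz=%d); axial sampling is coarser than lateral",
                axial, lateral, mz,
            )
        return mz


@dataclass
class RGCStack:
    """Per-frame radial-gradient-convergence maps on the magnified grid."""

    maps: np.ndarray  # T x (M H) x (M W), >= 0
    settings: ReconstructionSettings
    pixel_size_out: float  # nm per magnified pixel
    frame_interval: float = 0.01

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    @property
    def edge_border(self) -> int:
        return self.settings.edge_border


@dataclass
class SRImage:
    """A super-resolved image with its provenance metadata."""

    pixels: np.ndarray  # (M H) x (M W), >= 0
    pixel_size_out: float  # nm
    window: tuple  # [first_frame, last_frame] inclusive
    settings: ReconstructionSettings
    edge_border: int = 0


@dataclass
class SRVolume:
    """A super-resolved volume (Zm x Ym x Xm) with voxel metadata."""

    voxels: np.ndarray
    pixel_size_out: float  # nm lateral
    voxel_size_z: float  # nm axial
    window: tuple
    settings: Settings3D
    roi: Optional[tuple] = None  # (z0, z1, y0, y1, x0, x1) in output voxels


@dataclass
class PlaneRegistration:
    """Per-plane lateral shifts (row, col in raw pixels) against a reference plane."""

    shifts: np.ndarray  # Z x 2, (dy, dx)
    reference_plane: int
    residual_error: float = 0.0  # px, mean refit residual
    intensity_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise InvalidInputError("shifts must be Z x 2")

    @property
    def n_planes(self) -> int:
        return self.shifts.shape[0]


@dataclass
class FRCCurve:
    """Fourier ring correlation curve and the threshold-crossing resolution."""

    frequencies: np.ndarray  # ring-center spatial frequencies, 1/nm
    correlation: np.ndarray  # in [-1, 1]
    threshold: float
    resolution: float  # nm


@dataclass
class FidelityResult:
    """Resolution-scaled fidelity of a super-resolved image vs a reference."""

    rsp: float  # resolution-scaled Pearson correlation
    rse: float  # resolution-scaled error (RMS)
    sigma_rsf: float  # fitted Gaussian resolution-scaling width, nm
    alpha: float  # intensity scale
    beta: float  # intensity offset


@dataclass
class SweepResult:
    """Quality maps over the (R, S) reconstruction parameter grid."""

    radii: np.ndarray
    sensitivities: np.ndarray
    rsp: np.ndarray  # len(R) x len(S)
    frc_resolution: np.ndarray  # nm
    frc_sd: np.ndarray  # nm
    nfrc: np.ndarray  # [0, 1]
    qnr: np.ndarray  # [0, 1]
    best_radius: float
    best_sensitivity: float
    reconstructions: Optional[dict] = None  # (R, S) -> SRImage

    def reconstruction(self, radius: float, sensitivity: float) -> "SRImage":
        """Retrieve the stored reconstruction for one parameter cell."""
        if self.reconstructions is None:
            raise KeyError("sweep was run without keep_reconstructions=True")
        return self.reconstructions[(float(radius), float(sensitivity))]


@dataclass
class TSSIMTrace:
    """Structural-similarity trace against a reference frame, and the
    estimated largest motion-free frame window."""

    ssim: np.ndarray  # per-frame SSIM vs reference, in [-1, 1]
    window: int  # frames
    threshold: float


@dataclass
class GroundTruthScene:
    """Emitter positions (nm) with the scene extent; simulator ground truth."""

    coords: np.ndarray  # N x 2 (x, y) or N x 3 (x, y, z), nm
    extent: tuple  # (size_x, size_y[, size_z]) nm
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        if self.coords.shape[0] < 1:
            raise InvalidInputError("a scene needs at least one emitter")
        if self.coords.shape[1] not in (2, 3):
            raise InvalidInputError("coords must be N x 2 or N x 3")

    @property
    def n_emitters(self) -> int:
        return self.coords.shape[0]

    @property
    def is_3d(self) -> bool:
        return self.coords.shape[1] == 3


@dataclass
class BlinkKinetics:
    """Two-state blinking with photobleaching.

    Rates are s^-1: ``k_on`` (off->on), ``k_off`` (on->off), ``k_bleach``
    (exponential bleach-time draw, taking effect only from an on state),
    and the photon emission rate while on (photons/s).
    """

    k_on: float = 0.026
    k_off: float = 1.82
    k_bleach: float = 0.077
    photon_rate: float = 15.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_bleach", "photon_rate"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.k_on > 0 and self.k_off <= 0:
            raise InvalidParameterError("k_off must be > 0 when k_on > 0")

    @property
    def duty_cycle(self) -> float:
        """Stationary on-fraction k_on / (k_on + k_off)."""
        if self.k_on == 0:
            return 0.0
        return self.k_on / (self.k_on + self.k_off)


@dataclass
class CameraModel:
    """Exposure/read timing and read-out noise of the simulated camera."""

    exposure: float = 0.010  # s
    read_time: float = 0.005  # s
    pixel_size: float = 100.0  # nm
    read_noise: float = 1.0  # counts, Gaussian s.d.
    offset: float = 100.0  # counts

    def __post_init__(self) -> None:
        if not (self.exposure > 0):
            raise InvalidParameterError("exposure must be > 0")
        if self.read_time < 0:
            raise InvalidParameterError("read_time must be >= 0")
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel_size must be > 0")

    @property
    def frame_interval(self) -> float:
        return self.exposure + self.read_time


@dataclass
class PSFModel:
    """Gaussian PSF: lateral sigma = 0.21 * wavelength / NA, axial
    elongation ratio rho (axial sigma = rho * lateral sigma at focus)."""

    wavelength: float = 580.0  # nm, emission
    na: float = 1.4
    rho: float = 2.5

    def __post_init__(self) -> None:
        if not (self.wavelength > 0 and self.na > 0):
            raise InvalidParameterError("wavelength and NA must be > 0")
        if not (self.rho >= 1):
            raise InvalidParameterError("rho must be >= 1")

    @property
    def sigma(self) -> float:
        """Lateral Gaussian sigma in nm."""
        return 0.21 * self.wavelength / self.na

    def sigma_at_defocus(self, delta_z: float) -> float:
        """Lateral width at axial distance delta_z from focus (nm).

        Width-growth defocus model: sigma(z)^2 = sigma0^2 (1 + (z/zR)^2)
        with zR = rho * sigma0, so the peak intensity halves one zR away
        from focus.
        """
        s0 = self.sigma
        zr = self.rho * s0
        return s0 * math.sqrt(1.0 + (delta_z / zr) ** 2)
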