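"""Fluorescence-fluctuation simulators: phantoms, blinking kinetics, rendering.

The generators produce everything the reconstruction and quality modules
need for testing without external data: ground-truth emitter geometries
(fan pattern, crossing-filament woodpile, moving particle), continuous-time
two-state blinking with photobleaching, camera-frame binning with dead
time, Gaussian-PSF rendering with Poisson photon noise and Gaussian read
noise, and multiplane (MFM-style) imaging through a defocus-elongated PSF.

All randomness flows through an explicit ``numpy.random.Generator`` (or an
integer seed), making every simulation bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import erf

from .errors import InvalidInputError, InvalidParameterError
from .types import (
    BlinkKinetics,
    CameraModel,
    GroundTruthScene,
    ImageStack,
    PSFModel,
    VolumeStack,
)

__all__ = [
    "psf_sigma",
    "fan_pattern",
    "filament_pair",
    "woodpile",
    "BlinkTrace",
    "blink_trace",
    "bin_trace",
    "render_frames",
    "render_mfm",
    "diffusing_particle",
    "bin_frames",
]

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def psf_sigma(wavelength: float, na: float) -> float:
    """Gaussian PSF width sigma = 0.21 * wavelength / NA (nm)."""
    if not (wavelength > 0 and na > 0):
        raise InvalidParameterError("wavelength and NA must be > 0")
    return 0.21 * wavelength / na


# ---------------------------------------------------------------------------
# phantom geometries


def fan_pattern(
    ring_step: float = 220.0,
    separations: Sequence[float] = (57.5, 115.0, 173.0, 230.0, 288.0, 345.0),
    margin: float = 500.0,
) -> GroundTruthScene:
    """Concentric-ring resolution phantom.

    Ring k (1-based) has radius k * ring_step; its emitters are evenly
    spaced with arc separation separations[k-1], so the inner rings probe
    the smallest emitter distances.
    """
    if not (ring_step > 0):
        raise InvalidParameterError("ring_step must be > 0")
    separations = list(separations)
    if len(separations) < 1 or any(s <= 0 for s in separations):
        raise InvalidParameterError("separations must be positive")
    coords = []
    for k, sep in enumerate(separations, start=1):
        r = k * ring_step
        n = max(1, int(round(2.0 * math.pi * r / sep)))
        theta = 2.0 * math.pi * np.arange(n) / n
        coords.append(np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1))
    coords = np.concatenate(coords)
    half = len(separations) * ring_step + margin
    coords += half  # scene origin at the corner, center at (half, half)
    return GroundTruthScene(
        coords=coords,
        extent=(2 * half, 2 * half),
        label="fan_pattern",
        meta={"ring_step": ring_step, "separations": separations,
              "center": (half, half)},
    )


def filament_pair(
    separation: float = 150.0,
    length: float = 1200.0,
    linear_density: float = 0.02,
    margin: float = 400.0,
) -> GroundTruthScene:
    """Two parallel line filaments a fixed lateral distance apart (2D).

    ``linear_density`` is emitters per nm of filament; placement is regular
    so the density is exact up to rounding.
    """
    if separation <= 0 or length <= 0:
        raise InvalidParameterError("separation and length must be > 0")
    if linear_density <= 0:
        raise InvalidParameterError("linear_density must be > 0")
    n = max(2, int(round(length * linear_density)))
    x = np.linspace(0, length, n) + margin
    cy = margin + separation  # filaments at cy -/+ separation/2 around midline
    y1 = np.full(n, cy - separation / 2.0)
    y2 = np.full(n, cy + separation / 2.0)
    coords = np.concatenate([
        np.stack([x, y1], axis=1),
        np.stack([x, y2], axis=1),
    ])
    extent = (length + 2 * margin, 2 * cy)
    return GroundTruthScene(
        coords=coords, extent=extent, label="filament_pair",
        meta={"separation": separation, "midline_y": cy},
    )


def woodpile(
    z_separations: Sequence[float],
    lateral_spacing: float = 2000.0,
    emitter_linear_density: float = 0.01,
    filament_length: Optional[float] = None,
    z_center: float = 0.0,
) -> GroundTruthScene:
    """Crossing-filament 3D phantom with listed axial pair separations.

    For each separation s the scene holds one pair of orthogonal filaments:
    one along x at z = z_center - s/2, one along y at z = z_center + s/2,
    crossing above each other at the pair's lateral center.  Pairs are laid
    out on a row with ``lateral_spacing`` between crossing points; emitters
    populate the filaments at the given linear density (per nm).
    """
    z_separations = list(z_separations)
    if len(z_separations) == 0:
        raise InvalidParameterError("need at least one axial separation")
    if any(not (100.0 <= s <= 2000.0) for s in z_separations):
        raise InvalidParameterError("axial separations must lie in [100, 2000] nm")
    if emitter_linear_density <= 0:
        raise InvalidParameterError("emitter_linear_density must be > 0")
    if filament_length is None:
        filament_length = 0.8 * lateral_spacing
    if filament_length <= 0:
        raise InvalidParameterError("filament_length must be > 0")
    n_per = int(round(filament_length * emitter_linear_density))
    if n_per < 1:
        raise InvalidParameterError("filament too short for the given density")
    coords = []
    crossings = []
    half = lateral_spacing / 2.0
    for idx, s in enumerate(z_separations):
        cx = half + idx * lateral_spacing
        cy = half
        along = np.linspace(-filament_length / 2.0, filament_length / 2.0, n_per)
        lo, hi = z_center - s / 2.0, z_center + s / 2.0
        coords.append(np.stack([cx + along, np.full(n_per, cy), np.full(n_per, lo)], axis=1))
        coords.append(np.stack([np.full(n_per, cx), cy + along, np.full(n_per, hi)], axis=1))
        crossings.append((cx, cy))
    coords = np.concatenate(coords)
    extent = (len(z_separations) * lateral_spacing, lateral_spacing,
              max(z_separations) + 2000.0)
    return GroundTruthScene(
        coords=coords, extent=extent, label="woodpile",
        meta={"z_separations": z_separations, "crossings": crossings,
              "z_center": z_center, "filament_length": filament_length},
    )


# ---------------------------------------------------------------------------
# blinking kinetics


@dataclass
class BlinkTrace:
    """Continuous-time on/off trajectory of one molecule.

    ``bleach_time_drawn`` is the exponential photobleaching draw;
    ``bleach_time`` is the realized bleach moment (bleaching only takes
    effect from an on state, so a draw landing in an off interval defers to
    the next on-state entry).  Both are infinite for unbleached molecules.
    """

    on_intervals: List[Tuple[float, float]]
    bleach_time_drawn: float
    bleach_time: float
    duration: float

    @property
    def total_on_time(self) -> float:
        return float(sum(t1 - t0 for t0, t1 in self.on_intervals))


def blink_trace(kinetics: BlinkKinetics, duration: float, seed: RngLike) -> BlinkTrace:
    """Simulate one molecule's two-state telegraph trajectory.

    Dwell times are exponential (rate k_on for off->on, k_off for on->off);
    the initial state is drawn from the stationary distribution
    k_on/(k_on + k_off) to avoid transient bias in short simulations.  The
    trajectory is truncated at the bleach time (drawn from Exp(k_bleach),
    taking effect only from an on state) or at ``duration``.
    """
    if not (duration > 0):
        raise InvalidParameterError("duration must be > 0")
    rng = _rng(seed)
    k_on, k_off, k_bleach = kinetics.k_on, kinetics.k_off, kinetics.k_bleach
    bleach_drawn = rng.exponential(1.0 / k_bleach) if k_bleach > 0 else math.inf
    on = bool(rng.random() < kinetics.duty_cycle)
    t = 0.0
    intervals: List[Tuple[float, float]] = []
    bleach_real = math.inf
    while t < duration:
        if on:
            if bleach_drawn <= t:
                # draw landed in the preceding off interval: bleach now
                bleach_real = t
                break
            dwell = rng.exponential(1.0 / k_off) if k_off > 0 else math.inf
            end = min(t + dwell, duration)
            if bleach_drawn < end:
                intervals.append((t, bleach_drawn))
                bleach_real = bleach_drawn
                break
            intervals.append((t, end))
            t = end
            on = False
        else:
            if k_on <= 0:
                break
            dwell = rng.exponential(1.0 / k_on)
            t += dwell
            on = True
    return BlinkTrace(on_intervals=intervals, bleach_time_drawn=bleach_drawn,
                      bleach_time=bleach_real, duration=duration)


def bin_trace(trace: BlinkTrace, camera: CameraModel, n_frames: int) -> np.ndarray:
    """Per-frame on-fractions of a trajectory under the camera timing.

    Frame k integrates the on-time inside its exposure window
    [k*(exposure+read), k*(exposure+read) + exposure]; the read-time gap
    contributes nothing, and molecules switching mid-frame appear
    fractionally.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    period = camera.frame_interval
    needed = n_frames * period
    if trace.duration + 1e-12 < needed:
        raise InvalidInputError(
            f"trace covers {trace.duration:.3f}s but {n_frames} frames need {needed:.3f}s"
        )
    fractions = np.zeros(n_frames)
    if not trace.on_intervals:
        return fractions
    starts = np.array([t0 for t0, _ in trace.on_intervals])
    ends = np.array([t1 for _, t1 in trace.on_intervals])
    for k in range(n_frames):
        w0 = k * period
        w1 = w0 + camera.exposure
        overlap = np.clip(np.minimum(ends, w1) - np.maximum(starts, w0), 0.0, None)
        fractions[k] = overlap.sum() / camera.exposure
    return np.clip(fractions, 0.0, 1.0)


# ---------------------------------------------------------------------------
# rendering


def _gauss_pixel_profile(centers: np.ndarray, n_pix: int, pixel: float,
                         sigma: float) -> np.ndarray:
    """Analytic Gaussian integral over pixel bins, per emitter (N x n_pix)."""
    edges = np.arange(n_pix + 1) * pixel
    z = (edges[None, :] - centers[:, None]) / (math.sqrt(2.0) * sigma)
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf, axis=1)


def _render_plane(
    coords: np.ndarray,
    photons: np.ndarray,
    sigmas: np.ndarray,
    shape: Tuple[int, int],
    pixel: float,
) -> np.ndarray:
    """Expected-photon image of emitters with per-emitter widths."""
    h, w = shape
    img = np.zeros((h, w))
    active = photons > 0
    if not np.any(active):
        return img
    coords = coords[active]
    photons = photons[active]
    sigmas = sigmas[active]
    # group identical widths so each group renders as one outer product batch
    for s in np.unique(sigmas):
        sel = sigmas == s
        px = _gauss_pixel_profile(coords[sel, 0], w, pixel, s)
        py = _gauss_pixel_profile(coords[sel, 1], h, pixel, s)
        img += np.einsum("n,ny,nx->yx", photons[sel], py, px)
    return img


def _camera_noise(expected: np.ndarray, camera: CameraModel, rng: np.random.Generator,
                  poisson: bool, read_noise: bool) -> np.ndarray:
    out = rng.poisson(expected).astype(np.float64) if poisson else expected.copy()
    if read_noise and camera.read_noise > 0:
        out = out + rng.normal(0.0, camera.read_noise, size=out.shape)
    out = out + camera.offset
    return np.clip(out, 0.0, None)


def _frame_shape(scene: GroundTruthScene, camera: CameraModel) -> Tuple[int, int]:
    w = int(round(scene.extent[0] / camera.pixel_size))
    h = int(round(scene.extent[1] / camera.pixel_size))
    return h, w


def _fractions_matrix(traces: Sequence[BlinkTrace], camera: CameraModel,
                      n_frames: int) -> np.ndarray:
    return np.stack([bin_trace(tr, camera, n_frames) for tr in traces])


def render_frames(
    scene: GroundTruthScene,
    traces: Sequence[BlinkTrace],
    psf: PSFModel,
    camera: CameraModel,
    seed: RngLike,
    n_frames: Optional[int] = None,
    photon_rate: Optional[float] = None,
    poisson: bool = True,
    read_noise: bool = True,
) -> ImageStack:
    """Render a 2D blinking time series from a scene and its trajectories.

    Expected photons per emitter per frame are ``photon_rate * exposure *
    on_fraction``, spread as an analytically pixel-integrated Gaussian;
    Poisson photon noise, Gaussian read noise, and the camera offset are
    then applied.  Emitters outside the field are clipped with a warning.
    """
    rng = _rng(seed)
    if len(traces) != scene.n_emitters:
        raise InvalidInputError("need one trajectory per emitter")
    if photon_rate is None:
        photon_rate = 15.0
    h, w = _frame_shape(scene, camera)
    if h < 1 or w < 1:
        raise InvalidInputError("scene extent smaller than one camera pixel")
    coords = scene.coords[:, :2].copy()
    out_of_field = (
        (coords[:, 0] < 0) | (coords[:, 0] > scene.extent[0])
        | (coords[:, 1] < 0) | (coords[:, 1] > scene.extent[1])
    )
    if np.any(out_of_field):
        import warnings

        warnings.warn(f"{int(out_of_field.sum())} emitters outside the field; clipping")
        coords[:, 0] = np.clip(coords[:, 0], 0, scene.extent[0])
        coords[:, 1] = np.clip(coords[:, 1], 0, scene.extent[1])
    if n_frames is None:
        n_frames = int(min(tr.duration for tr in traces) / camera.frame_interval)
    fractions = _fractions_matrix(traces, camera, n_frames)
    sigma = psf.sigma
    sigmas = np.full(scene.n_emitters, sigma)
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        photons = photon_rate * camera.exposure * fractions[:, t]
        expected = _render_plane(coords, photons, sigmas, (h, w), camera.pixel_size)
        frames[t] = _camera_noise(expected, camera, rng, poisson, read_noise)
    return ImageStack(frames=frames, pixel_size=camera.pixel_size,
                      frame_interval=camera.frame_interval)


def render_mfm(
    scene: GroundTruthScene,
    traces: Sequence[BlinkTrace],
    psf: PSFModel,
    camera: CameraModel,
    seed: RngLike,
    n_planes: int = 9,
    dz: float = 390.0,
    n_frames: Optional[int] = None,
    photon_rate: Optional[float] = None,
    z_center: float = 0.0,
    poisson: bool = True,
    read_noise: bool = True,
) -> VolumeStack:
    """Render a multiplane (MFM-style) time series of a 3D scene.

    All planes share the frame timing (simultaneous acquisition).  Each
    plane images every emitter through the elongated-Gaussian PSF focused
    at the plane's depth: the lateral width grows with defocus as
    sigma(z)^2 = sigma0^2 (1 + (dz_/zR)^2), zR = rho * sigma0, while the
    total collected flux per plane is conserved (wide-field detection), so
    an in-focus plane shows the brightest, tightest spot.
    """
    if n_planes < 2:
        raise InvalidParameterError("n_planes must be >= 2")
    if not scene.is_3d:
        raise InvalidInputError("render_mfm needs a 3D scene")
    if len(traces) != scene.n_emitters:
        raise InvalidInputError("need one trajectory per emitter")
    if photon_rate is None:
        photon_rate = 15.0
    rng = _rng(seed)
    h, w = _frame_shape(scene, camera)
    coords = scene.coords[:, :2]
    zs = scene.coords[:, 2]
    plane_focus = z_center + (np.arange(n_planes) - (n_planes - 1) / 2.0) * dz
    if n_frames is None:
        n_frames = int(min(tr.duration for tr in traces) / camera.frame_interval)
    fractions = _fractions_matrix(traces, camera, n_frames)
    # per-plane per-emitter defocused widths, rounded to limit unique widths
    sig = np.empty((n_planes, scene.n_emitters))
    for p in range(n_planes):
        sig[p] = [psf.sigma_at_defocus(z - plane_focus[p]) for z in zs]
    sig = np.round(sig, 1)
    frames = np.empty((n_frames, n_planes, h, w))
    for t in range(n_frames):
        photons = photon_rate * camera.exposure * fractions[:, t]
        for p in range(n_planes):
            expected = _render_plane(coords, photons, sig[p], (h, w), camera.pixel_size)
            frames[t, p] = _camera_noise(expected, camera, rng, poisson, read_noise)
    return VolumeStack(frames=frames, pixel_size=camera.pixel_size, dz=dz,
                       frame_interval=camera.frame_interval)


def diffusing_particle(
    speed: float,
    direction: Tuple[float, float],
    duration: float,
    psf: PSFModel,
    camera: CameraModel,
    seed: RngLike,
    field: Tuple[float, float] = (3200.0, 3200.0),
    start: Optional[Tuple[float, float]] = None,
    photon_rate: float = 15000.0,
) -> Tuple[ImageStack, np.ndarray]:
    """A single always-on emitter moving at constant speed (nm/s).

    Returns the rendered stack and the ground-truth path (n_frames x 2,
    the position at each frame's exposure midpoint).  If the path exits the
    field the stack is truncated there with a warning.
    """
    if speed < 0:
        raise InvalidParameterError("speed must be >= 0")
    rng = _rng(seed)
    direction = np.asarray(direction, dtype=np.float64)
    norm = np.hypot(*direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
    if start is None:
        start = (field[0] * 0.25, field[1] * 0.5)
    n_frames = max(1, int(duration / camera.frame_interval))
    t_mid = (np.arange(n_frames) + 0.5) * camera.frame_interval
    path = np.asarray(start)[None, :] + speed * t_mid[:, None] * direction[None, :]
    inside = (
        (path[:, 0] >= 0) & (path[:, 0] <= field[0])
        & (path[:, 1] >= 0) & (path[:, 1] <= field[1])
    )
    if not np.all(inside):
        import warnings

        n_keep = int(np.argmin(inside)) if not inside.all() else n_frames
        warnings.warn(f"path exits the field at frame {n_keep}; truncating")
        n_frames = max(1, n_keep)
        path = path[:n_frames]
    h = int(round(field[1] / camera.pixel_size))
    w = int(round(field[0] / camera.pixel_size))
    sigma = np.array([psf.sigma])
    photons = np.array([photon_rate * camera.exposure])
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        expected = _render_plane(path[t][None, :], photons, sigma, (h, w),
                                 camera.pixel_size)
        frames[t] = _camera_noise(expected, camera, rng, True, True)
    stack = ImageStack(frames=frames, pixel_size=camera.pixel_size,
                       frame_interval=camera.frame_interval)
    return stack, path


def bin_frames(stack: ImageStack, factor: int, reduce: str = "mean") -> ImageStack:
    """Temporal binning (density escalation): group frames by ``factor``.

    Averaging ``factor`` consecutive frames multiplies the apparent
    per-frame emitter density by ``factor`` while keeping the intensity
    scale; ``reduce="sum"`` accumulates counts instead.
    """
    if factor < 1:
        raise InvalidParameterError("factor must be >= 1")
    t = stack.n_frames
    n = t // factor
    if n < 1:
        raise InvalidInputError(f"cannot bin {t} frames by {factor}")
    grouped = stack.frames[: n * factor].reshape(n, factor, *stack.frames.shape[1:])
    frames = grouped.sum(axis=1) if reduce == "sum" else grouped.mean(axis=1)
    return ImageStack(frames=frames, pixel_size=stack.pixel_size,
                      frame_interval=stack.frame_interval * factor)
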