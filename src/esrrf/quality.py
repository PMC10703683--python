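"""Data-driven reconstruction assessment and parameter optimization.

Resolution is estimated by Fourier ring correlation (FRC) between two
statistically independent reconstructions (even vs odd frames of the raw
series); fidelity by the resolution-scaled Pearson correlation (RSP): the
super-resolved image is blurred back to the reference resolution with a
fitted Gaussian and compared to the wide-field mean.  The two are combined
per (R, S) parameter cell into the QnR score, their harmonic (F1) mean

    QnR = 2 * RSP * nFRC / (RSP + nFRC),

where nFRC maps the FRC resolution onto [0, 1] (1 = best resolution in the
sweep).  A temporal structural-similarity trace (tSSIM) bounds the frame
window usable before sample motion blurs the reconstruction.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize_scalar
from skimage.filters import window as skimage_window
from skimage.metrics import structural_similarity

from .errors import (
    InsufficientFramesError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .interpolation import fourier_interpolate
from .temporal import reconstruct
from .types import (
    FidelityResult,
    FRCCurve,
    ImageStack,
    ReconstructionSettings,
    SRImage,
    SweepResult,
    TemporalMode,
    TSSIMTrace,
)

logger = logging.getLogger(__name__)

__all__ = [
    "split_even_odd",
    "frc_resolution",
    "blockwise_frc",
    "rsp_rse",
    "qnr",
    "parameter_sweep",
    "tssim",
]

FRC_THRESHOLD = 1.0 / 7.0  # community-standard fixed threshold


def split_even_odd(stack: ImageStack) -> Tuple[ImageStack, ImageStack]:
    """Split a raw series into the even-index and odd-index frame substacks.

    The two halves are statistically independent samples of the same
    structure, the input pair for FRC resolution estimation.
    """
    if stack.n_frames < 2:
        raise InsufficientFramesError("even/odd split needs at least 2 frames")
    even = ImageStack(stack.frames[0::2], stack.pixel_size, stack.frame_interval)
    odd = ImageStack(stack.frames[1::2], stack.pixel_size, stack.frame_interval)
    return even, odd


def _frc_curve(img_a: np.ndarray, img_b: np.ndarray, pixel_size: float,
               apodize: bool) -> Tuple[np.ndarray, np.ndarray]:
    h, w = img_a.shape
    a = img_a.astype(np.float64)
    b = img_b.astype(np.float64)
    if apodize:
        win = skimage_window("hann", (h, w))
        a = a * win
        b = b * win
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    fy = np.fft.fftfreq(h, d=pixel_size)[:, None]
    fx = np.fft.fftfreq(w, d=pixel_size)[None, :]
    f = np.hypot(fy, fx)
    df = 1.0 / (min(h, w) * pixel_size)  # one ring per FFT bin of the short axis
    ring = np.floor(f / df + 0.5).astype(np.int64)
    n_rings = int(min(h, w) // 2) + 1
    mask = ring < n_rings
    idx = ring[mask]
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real[mask], minlength=n_rings)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2)[mask], minlength=n_rings)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2)[mask], minlength=n_rings)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where(denom > 0, cross / denom, 0.0)
    freqs = np.arange(n_rings) * df
    return freqs, frc


def frc_resolution(
    img_a: np.ndarray,
    img_b: np.ndarray,
    pixel_size_out: float,
    threshold: float = FRC_THRESHOLD,
    apodize: bool = True,
) -> FRCCurve:
    """Fourier ring correlation resolution of an independent image pair.

    The ring-averaged normalized cross-spectrum is scanned for its first
    crossing below ``threshold`` (linear interpolation between rings); the
    resolution is the inverse of that frequency, capped at twice the output
    pixel size (the Nyquist wavelength) when the correlation never drops.

    A Hann apodization suppresses spectral leakage from the image borders;
    it never changes the identical-image case (curve identically 1).
    """
    img_a = np.asarray(img_a, dtype=np.float64)
    img_b = np.asarray(img_b, dtype=np.float64)
    if img_a.shape != img_b.shape or img_a.ndim != 2:
        raise InvalidInputError("FRC needs two 2-D images of identical shape")
    if not np.any(img_a) or not np.any(img_b):
        raise InvalidInputError("FRC input images must not be identically zero")
    freqs, frc = _frc_curve(img_a, img_b, pixel_size_out, apodize)
    cap = 2.0 * pixel_size_out
    resolution = cap
    below = np.nonzero(frc[1:] < threshold)[0]
    if below.size:
        i = below[0] + 1  # first ring below threshold (skip DC)
        f0, f1 = freqs[i - 1], freqs[i]
        c0, c1 = frc[i - 1], frc[i]
        fc = f0 if c0 == c1 else f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
        if fc > 0:
            resolution = max(1.0 / fc, cap)
    return FRCCurve(frequencies=freqs, correlation=frc, threshold=threshold,
                    resolution=resolution)


def blockwise_frc(
    img_a: np.ndarray,
    img_b: np.ndarray,
    pixel_size_out: float,
    blocks: int = 2,
    threshold: float = FRC_THRESHOLD,
) -> Tuple[float, float]:
    """Mean and s.d. of the FRC resolution over a blocks x blocks partition."""
    if blocks < 1:
        raise InvalidParameterError("blocks must be >= 1")
    img_a = np.asarray(img_a, dtype=np.float64)
    img_b = np.asarray(img_b, dtype=np.float64)
    if img_a.shape != img_b.shape or img_a.ndim != 2:
        raise InvalidInputError("blockwise FRC needs two equal-shape 2-D images")
    h, w = img_a.shape
    th, tw = h // blocks, w // blocks
    if th < 64 or tw < 64:
        raise InvalidParameterError(
            f"{blocks}x{blocks} tiles of a {h}x{w} image are {th}x{tw}; "
            "subregions must be at least 64x64 magnified pixels"
        )
    vals = []
    for bi in range(blocks):
        for bj in range(blocks):
            ta = img_a[bi * th: (bi + 1) * th, bj * tw: (bj + 1) * tw]
            tb = img_b[bi * th: (bi + 1) * th, bj * tw: (bj + 1) * tw]
            vals.append(frc_resolution(ta, tb, pixel_size_out, threshold).resolution)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xm * ym).sum() / denom)


def rsp_rse(
    sr: SRImage,
    reference_wf: np.ndarray,
    sigma_bounds_px: Tuple[float, float] = (0.0, 10.0),
) -> FidelityResult:
    """Resolution-scaled Pearson fidelity and error against a wide-field
    reference (the temporal mean of the raw stack on the magnified grid).

    The resolution-scaling function (RSF) is a Gaussian whose width is
    fitted by a bounded 1-D search maximizing the Pearson correlation of
    the blurred super-resolved image with the reference (the lower bound
    includes the delta-kernel limit, so an image identical to its
    reference scores RSP = 1 exactly); the intensity scale/offset
    (alpha, beta) follow by closed-form least squares and only enter the
    error term.
    """
    ref = np.asarray(reference_wf, dtype=np.float64)
    img = np.asarray(sr.pixels, dtype=np.float64)
    if ref.shape != img.shape:
        raise InvalidInputError("reference and super-resolved image shapes differ")
    if np.ptp(ref) == 0:
        raise UndefinedCorrelationError("reference image is constant")

    def neg_corr(sigma_px: float) -> float:
        return -_pearson(gaussian_filter(img, sigma_px), ref)

    res = minimize_scalar(neg_corr, bounds=sigma_bounds_px, method="bounded",
                          options={"xatol": 1e-2})
    sigma_px = float(res.x)
    blurred = gaussian_filter(img, sigma_px)
    rsp = _pearson(blurred, ref)
    # least-squares intensity mapping alpha * blurred + beta -> reference
    a_mat = np.stack([blurred.ravel(), np.ones(blurred.size)], axis=1)
    coef, *_ = np.linalg.lstsq(a_mat, ref.ravel(), rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    rse = float(np.sqrt(np.mean((alpha * blurred + beta - ref) ** 2)))
    return FidelityResult(rsp=rsp, rse=rse, sigma_rsf=sigma_px * sr.pixel_size_out,
                          alpha=alpha, beta=beta)


def qnr(rsp: float, nfrc: float) -> float:
    """Quality-and-resolution score: harmonic (F1) mean of RSP and nFRC."""
    if not (0.0 <= rsp <= 1.0 and 0.0 <= nfrc <= 1.0):
        raise InvalidParameterError("qnr inputs must lie in [0, 1]")
    if rsp + nfrc == 0.0:
        return 0.0
    return 2.0 * rsp * nfrc / (rsp + nfrc)


def _interpolated_reference(stack: ImageStack, magnification: int) -> np.ndarray:
    return fourier_interpolate(stack.mean_image(), magnification)


def parameter_sweep(
    stack: ImageStack,
    magnification: int,
    radii: Sequence[float],
    sensitivities: Sequence[float],
    temporal_mode: TemporalMode = TemporalMode.VAR,
    blocks: Optional[int] = None,
    keep_reconstructions: bool = True,
) -> SweepResult:
    """Explore the (R, S) space: FRC resolution, RSP fidelity, QnR per cell.

    For each cell, the even and odd half-series are reconstructed with
    identical settings and their blockwise FRC gives the resolution; the
    full-series reconstruction is compared to the interpolated wide-field
    mean for the RSP.  nFRC is the per-sweep min-max normalization of the
    resolution (best resolution -> 1); QnR combines the two, and the argmax
    cell is reported.  Cell reconstructions are retained for inspection
    unless ``keep_reconstructions`` is disabled.
    """
    radii = np.asarray(list(radii), dtype=np.float64)
    sensitivities = np.asarray(list(sensitivities), dtype=np.float64)
    if radii.size == 0 or sensitivities.size == 0:
        raise InvalidParameterError("radius and sensitivity grids must be non-empty")
    even, odd = split_even_odd(stack)
    reference = _interpolated_reference(stack, magnification)
    mag_h = stack.frames.shape[1] * magnification
    mag_w = stack.frames.shape[2] * magnification
    if blocks is None:
        blocks = 2 if min(mag_h, mag_w) // 2 >= 64 else 1
        if blocks == 1:
            logger.info("image too small for 2x2 FRC tiles; using whole-image FRC")

    shape = (radii.size, sensitivities.size)
    rsp_map = np.zeros(shape)
    res_map = np.zeros(shape)
    sd_map = np.zeros(shape)
    recons: dict = {}
    for i, r in enumerate(radii):
        for j, s in enumerate(sensitivities):
            settings = ReconstructionSettings(
                magnification=magnification, radius=float(r), sensitivity=float(s),
                temporal_mode=temporal_mode,
            )
            sr_even = reconstruct(even, settings)
            sr_odd = reconstruct(odd, settings)
            mean_res, sd_res = blockwise_frc(
                sr_even.pixels, sr_odd.pixels, sr_even.pixel_size_out, blocks=blocks
            )
            sr_full = reconstruct(stack, settings)
            fid = rsp_rse(sr_full, reference)
            rsp_map[i, j] = fid.rsp
            res_map[i, j] = mean_res
            sd_map[i, j] = sd_res
            if keep_reconstructions:
                recons[(float(r), float(s))] = sr_full

    worst, best = res_map.max(), res_map.min()
    if worst == best:
        nfrc_map = np.ones(shape)
    else:
        nfrc_map = (worst - res_map) / (worst - best)
    qnr_map = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            qnr_map[i, j] = qnr(float(np.clip(rsp_map[i, j], 0.0, 1.0)),
                                float(nfrc_map[i, j]))
    bi, bj = np.unravel_index(np.argmax(qnr_map), shape)
    return SweepResult(
        radii=radii, sensitivities=sensitivities,
        rsp=rsp_map, frc_resolution=res_map, frc_sd=sd_map,
        nfrc=nfrc_map, qnr=qnr_map,
        best_radius=float(radii[bi]), best_sensitivity=float(sensitivities[bj]),
        reconstructions=recons if keep_reconstructions else None,
    )


def tssim(
    stack: ImageStack,
    quality_factor: float = 0.8,
    baseline_fraction: float = 0.05,
) -> TSSIMTrace:
    """Temporal structural-similarity trace and motion-free window estimate.

    SSIM of every frame against the first frame (Gaussian 1.5 px window,
    K1 = 0.01, K2 = 0.03, dynamic range from the stack's global min/max).
    The usable frame window is the longest initial run whose SSIM stays at
    or above ``quality_factor`` times the median SSIM of the earliest
    ``baseline_fraction`` of frames - past that point the structure has
    measurably moved and longer windows would blur the reconstruction.
    """
    t = stack.n_frames
    if t < 3:
        raise InsufficientFramesError("tSSIM needs at least 3 frames")
    data_range = float(np.ptp(stack.frames))
    if data_range == 0:
        return TSSIMTrace(ssim=np.ones(t), window=t, threshold=1.0)
    ref = stack.frames[0]
    trace = np.empty(t)
    for i in range(t):
        trace[i] = structural_similarity(
            ref, stack.frames[i], data_range=data_range,
            gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            K1=0.01, K2=0.03,
        )
    n0 = max(2, int(np.ceil(baseline_fraction * t)))
    baseline = float(np.median(trace[1: n0 + 1]))
    threshold = quality_factor * baseline
    below = np.nonzero(trace < threshold)[0]
    window = int(below[0]) if below.size else t
    window = int(np.clip(window, 2, t))
    return TSSIMTrace(ssim=trace, window=window, threshold=threshold)
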