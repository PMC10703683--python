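"""Temporal compression of RGC stacks and rolling-window reconstruction.

A stack of per-frame RGC maps carries the emitter fluctuations; compressing
it along time yields the super-resolved image.  Three compressions are
provided: the mean (AVG), the population variance (VAR, the default - the
fluctuation signal itself), and the lag-1 second-order auto-cumulant (TAC2,
a cross-correlation that rejects uncorrelated noise).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .errors import InsufficientFramesError, InvalidParameterError
from .rgc import rgc_stack
from .types import ImageStack, ReconstructionSettings, RGCStack, SRImage, TemporalMode

__all__ = ["compress", "reconstruct", "rolling_reconstruct", "temporal_project"]


def temporal_project(maps: np.ndarray, mode: TemporalMode, lag: int = 1) -> np.ndarray:
    """Per-pixel temporal statistic of a (T, ...) array.

    AVG is the mean; VAR the population (1/T) variance, stable at small T;
    TAC2 the mean of the mean-subtracted lag products, clamped at zero
    (a signed map is not displayable as an intensity).
    """
    mode = TemporalMode(mode)
    t = maps.shape[0]
    if mode is TemporalMode.AVG:
        if t < 1:
            raise InsufficientFramesError("AVG needs at least 1 frame")
        return maps.mean(axis=0)
    if t < 2:
        raise InsufficientFramesError(f"{mode.value} needs at least 2 frames")
    if mode is TemporalMode.VAR:
        return maps.var(axis=0)
    # TAC2
    if not (1 <= lag < t):
        raise InvalidParameterError(f"lag must be in [1, T-1], got {lag}")
    delta = maps - maps.mean(axis=0)
    tac = (delta[:-lag] * delta[lag:]).mean(axis=0)
    return np.clip(tac, 0.0, None)


def compress(rgc: RGCStack, mode: Optional[TemporalMode] = None, lag: int = 1) -> SRImage:
    """Compress an RGC stack into one super-resolved image."""
    if mode is None:
        mode = rgc.settings.temporal_mode
    pixels = temporal_project(rgc.maps, mode, lag=lag)
    return SRImage(
        pixels=pixels,
        pixel_size_out=rgc.pixel_size_out,
        window=(0, rgc.n_frames - 1),
        settings=rgc.settings,
        edge_border=rgc.edge_border,
    )


def reconstruct(
    stack: ImageStack,
    settings: Optional[ReconstructionSettings] = None,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> SRImage:
    """Full pipeline: raw stack -> RGC stack -> temporally compressed image."""
    if settings is None:
        settings = ReconstructionSettings()
    return compress(rgc_stack(stack, settings, roi=roi), settings.temporal_mode)


def rolling_reconstruct(
    stack: ImageStack,
    settings: ReconstructionSettings,
    window: int,
    stride: Optional[int] = None,
) -> List[SRImage]:
    """Super-resolved time series from overlapping frame windows.

    The k-th image is reconstructed from frames [k*stride, k*stride+window);
    there are floor((T - window)/stride) + 1 of them.  Default stride is
    window/10 rounded up.
    """
    t = stack.n_frames
    if window > t:
        raise InsufficientFramesError(f"window {window} exceeds stack length {t}")
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    if stride is None:
        stride = max(1, -(-window // 10))
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    out: List[SRImage] = []
    for k in range((t - window) // stride + 1):
        first = k * stride
        sub = ImageStack(
            frames=stack.frames[first: first + window],
            pixel_size=stack.pixel_size,
            frame_interval=stack.frame_interval,
        )
        img = reconstruct(sub, settings)
        img.window = (first, first + window - 1)
        out.append(img)
    return out
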