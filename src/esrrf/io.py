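"""TIFF input/output, run manifests, and sweep exports.

TIFF is the only mandatory format (the field standard for microscopy
stacks).  Axis order is always declared by the caller, never guessed
silently; the pixel size is taken from ImageJ-style tags when present and
otherwise must come from the caller, with mismatches logged.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .errors import FormatError, InvalidParameterError
from .types import (
    ImageStack,
    PlaneRegistration,
    SRImage,
    SRVolume,
    SweepResult,
    VolumeStack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_outputs",
    "write_stack",
    "write_sr_image",
    "write_sr_volume",
    "write_sweep",
    "write_registration",
    "read_registration",
]

_AXES_2D = {"TYX", "YX"}
_AXES_3D = {"TZYX", "ZYX"}


def _tiff_pixel_size_nm(tif: "tifffile.TiffFile") -> Optional[float]:
    """Best-effort pixel size from ImageJ metadata / resolution tags (nm)."""
    try:
        page = tif.pages[0]
        tags = page.tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            if num:
                unit = tags.get("ResolutionUnit")
                per_px = den / num  # in resolution units
                scale = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", None), None)
                if scale:
                    return per_px * scale
                ij = tif.imagej_metadata or {}
                if ij.get("unit") in ("micron", "um", "µm"):
                    return per_px * 1e3
                if ij.get("unit") == "nm":
                    return per_px
    except Exception:  # metadata is advisory only
        pass
    return None


def read_stack(
    path: Union[str, Path],
    axes: str,
    pixel_size: Optional[float] = None,
    frame_interval: float = 0.01,
    dz: Optional[float] = None,
) -> Union[ImageStack, VolumeStack]:
    """Read a multi-page TIFF as an ImageStack (TYX) or VolumeStack (TZYX).

    ``axes`` declares the dimension order explicitly.  Integer samples are
    converted losslessly to float64.  The pixel size (nm) is read from the
    file's tags when available; a caller-provided value wins, and any
    disagreement is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    axes = axes.upper()
    if axes not in _AXES_2D | _AXES_3D:
        raise FormatError(
            f"axes {axes!r} not understood; declare one of TYX, YX, TZYX, ZYX"
        )
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            tag_px = _tiff_pixel_size_nm(tif)
    except Exception as exc:
        raise FormatError(
            f"could not read {path} as TIFF ({exc}); is it an uncompressed "
            "multi-page TIFF with the declared axis order?"
        ) from exc
    data = np.asarray(data, dtype=np.float64)
    if pixel_size is None:
        pixel_size = tag_px
    elif tag_px is not None and abs(tag_px - pixel_size) > 0.01 * pixel_size:
        logger.warning("pixel size %.1f nm from tags differs from declared %.1f nm; "
                       "using the declared value", tag_px, pixel_size)
    if pixel_size is None:
        raise FormatError(
            f"{path} carries no readable pixel size; pass pixel_size= explicitly"
        )
    if axes == "YX":
        data = data[None]
        axes = "TYX"
    if axes == "ZYX":
        data = data[None]
        axes = "TZYX"
    if data.ndim != len(axes):
        raise FormatError(
            f"file has {data.ndim} dimensions but axes {axes!r} declare {len(axes)}"
        )
    if axes == "TYX":
        return ImageStack(frames=data, pixel_size=pixel_size,
                          frame_interval=frame_interval)
    if dz is None:
        raise FormatError("volumetric input needs the inter-plane offset dz=")
    return VolumeStack(frames=data, pixel_size=pixel_size, dz=dz,
                       frame_interval=frame_interval)


def write_stack(array: np.ndarray, path: Union[str, Path]) -> Path:
    """Write an array as a 32-bit float multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def _manifest(settings, seed=None, extra=None) -> dict:
    from . import __version__

    man = {"package": "esrrf", "version": __version__}
    if settings is not None:
        man["settings"] = {
            k: (v.value if hasattr(v, "value") else v)
            for k, v in asdict(settings).items()
        }
    if seed is not None:
        man["seed"] = int(seed)
    if extra:
        man.update(extra)
    return man


def write_sr_image(sr: SRImage, out_dir: Union[str, Path], name: str = "esrrf",
                   seed: Optional[int] = None) -> dict:
    """Write a super-resolved image as TIFF plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = write_stack(sr.pixels, out_dir / f"{name}.tif")
    manifest = _manifest(sr.settings, seed, {
        "pixel_size_out_nm": sr.pixel_size_out,
        "frame_window": list(sr.window),
        "edge_border_px": sr.edge_border,
    })
    man_path = out_dir / f"{name}.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"tiff": tif, "manifest": man_path}


def write_sr_volume(sr: SRVolume, out_dir: Union[str, Path], name: str = "esrrf3d",
                    seed: Optional[int] = None) -> dict:
    """Write a super-resolved volume as a Z-stacked TIFF plus manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = write_stack(sr.voxels, out_dir / f"{name}.tif")
    manifest = _manifest(sr.settings, seed, {
        "pixel_size_out_nm": sr.pixel_size_out,
        "voxel_size_z_nm": sr.voxel_size_z,
        "frame_window": list(sr.window),
        "roi": list(sr.roi) if sr.roi else None,
    })
    man_path = out_dir / f"{name}.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"tiff": tif, "manifest": man_path}


def write_sweep(sweep: SweepResult, out_dir: Union[str, Path],
                seed: Optional[int] = None) -> dict:
    """Export sweep maps as TIFFs plus a CSV summary and JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("qnr", sweep.qnr), ("rsp", sweep.rsp),
                      ("frc_resolution", sweep.frc_resolution),
                      ("nfrc", sweep.nfrc)):
        paths[name] = write_stack(arr, out_dir / f"sweep_{name}.tif")
    csv_path = out_dir / "sweep_summary.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["radius", "sensitivity", "rsp", "frc_resolution_nm",
                         "frc_sd_nm", "nfrc", "qnr"])
        for i, r in enumerate(sweep.radii):
            for j, s in enumerate(sweep.sensitivities):
                writer.writerow([r, s, sweep.rsp[i, j], sweep.frc_resolution[i, j],
                                 sweep.frc_sd[i, j], sweep.nfrc[i, j], sweep.qnr[i, j]])
    manifest = _manifest(None, seed, {
        "radii": list(map(float, sweep.radii)),
        "sensitivities": list(map(float, sweep.sensitivities)),
        "best_radius": sweep.best_radius,
        "best_sensitivity": sweep.best_sensitivity,
    })
    man_path = out_dir / "sweep_summary.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths.update({"csv": csv_path, "manifest": man_path})
    return paths


def write_outputs(result, out_dir: Union[str, Path],
                  seed: Optional[int] = None) -> dict:
    """Write any pipeline result (SR image, SR volume, or sweep) to disk.

    Dispatches on the result type; returns the paths written.
    """
    if isinstance(result, SRImage):
        return write_sr_image(result, out_dir, seed=seed)
    if isinstance(result, SRVolume):
        return write_sr_volume(result, out_dir, seed=seed)
    if isinstance(result, SweepResult):
        return write_sweep(result, out_dir, seed=seed)
    raise InvalidParameterError(f"no writer for result type {type(result).__name__}")


def write_registration(reg: PlaneRegistration, path: Union[str, Path]) -> Path:
    """Save a plane-registration table as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "shifts": reg.shifts.tolist(),
        "reference_plane": reg.reference_plane,
        "residual_error": reg.residual_error,
    }
    if reg.intensity_scale is not None:
        payload["intensity_scale"] = list(map(float, reg.intensity_scale))
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_registration(path: Union[str, Path]) -> PlaneRegistration:
    payload = json.loads(Path(path).read_text())
    scale = payload.get("intensity_scale")
    return PlaneRegistration(
        shifts=np.asarray(payload["shifts"], dtype=np.float64),
        reference_plane=int(payload["reference_plane"]),
        residual_error=float(payload.get("residual_error", 0.0)),
        intensity_scale=np.asarray(scale) if scale is not None else None,
    )
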