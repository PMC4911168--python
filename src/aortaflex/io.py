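"""Calibrated image-series containers and their on-disk formats.

Two containers flow through the pipeline: :class:`CineSeries` (bright-blood
anatomical frames) and :class:`VelocitySeries` (through-plane velocity maps).
Both carry the spatial calibration in mm/pixel and per-frame timestamps in ms.
Series are stored either as NIfTI (time along the 4th axis, mm/ms units in the
header) or as multi-page TIFF; in both cases a JSON sidecar carries the full
metadata and is authoritative when present.

Unit conventions used package-wide: lengths mm, areas mm2, times ms, pressures
mmHg, velocities mm/ms. 1 mm/ms == 1 m/s, so PWV needs no conversion factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


class SeriesFormatError(ValueError):
    """Raised when a series file is missing required calibration."""


@dataclass
class CineSeries:
    """Time-resolved 2-D image stack of one aortic plane.

    frames: (n_frames, rows, cols) intensities; pixel_mm: isotropic pixel
    size; frame_times: ms from the R-wave, strictly increasing.
    """

    frames: np.ndarray
    pixel_mm: float
    frame_times: np.ndarray
    plane: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, rows, cols)")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frame_times length must match number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class VelocitySeries:
    """Through-plane velocity stack, congruent with a paired CineSeries.

    Values are velocities in mm/ms, clipped to ±venc by acquisition.
    """

    frames: np.ndarray
    venc: float
    pixel_mm: float
    frame_times: np.ndarray
    plane: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, rows, cols)")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frame_times length must match number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.venc <= 0 or self.pixel_mm <= 0:
            raise ValueError("venc and pixel_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _metadata(series: CineSeries | VelocitySeries) -> dict:
    meta = {
        "kind": "velocity" if isinstance(series, VelocitySeries) else "cine",
        "pixel_mm": float(series.pixel_mm),
        "frame_times_ms": [float(t) for t in series.frame_times],
        "plane": series.plane,
        "provenance": series.provenance,
    }
    if isinstance(series, VelocitySeries):
        meta["venc_mm_per_ms"] = float(series.venc)
    return meta


def write_series(series: CineSeries | VelocitySeries, path: str | Path) -> Path:
    """Write a series as NIfTI (.nii/.nii.gz) or TIFF (.tif/.tiff) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = _metadata(series)
    if path.name.endswith((".nii", ".nii.gz")):
        # NIfTI axis order (x, y, z, t); frames map to (col, row, 1, time)
        data = np.transpose(series.frames, (2, 1, 0))[:, :, np.newaxis, :]
        dt = float(np.median(np.diff(series.frame_times)))
        affine = np.diag([series.pixel_mm, series.pixel_mm, 1.0, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(data), affine)
        img.header.set_zooms((series.pixel_mm, series.pixel_mm, 1.0, dt))
        img.header.set_xyzt_units(xyz="mm", t="msec")
        nib.save(img, str(path))
    elif path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), series.frames.astype(np.float32),
                         photometric="minisblack")
    else:
        raise SeriesFormatError(f"unsupported series container: {path.name}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_series(path: str | Path) -> CineSeries | VelocitySeries:
    """Read a series written by :func:`write_series`.

    The JSON sidecar is authoritative for calibration. A bare NIfTI without a
    sidecar is accepted if its header carries spatial and temporal spacing; a
    missing temporal spacing is an error, never a silent default.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None

    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 4:
            data = data[:, :, 0, :]
        frames = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()
        hdr_pixel = float(zooms[0])
        hdr_dt = float(zooms[3]) if len(zooms) >= 4 else 0.0
        t_unit = img.header.get_xyzt_units()[1]
        if t_unit == "sec":
            hdr_dt *= 1000.0
        elif t_unit != "msec":
            hdr_dt = 0.0  # untyped temporal axis: treat spacing as missing
    elif path.name.endswith((".tif", ".tiff")):
        frames = np.asarray(tifffile.imread(str(path)), dtype=float)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        hdr_pixel = hdr_dt = 0.0
        if meta is None:
            raise SeriesFormatError(f"TIFF series requires a JSON sidecar: {sidecar}")
    else:
        raise SeriesFormatError(f"unsupported series container: {path.name}")

    if meta is not None:
        if "pixel_mm" not in meta:
            raise SeriesFormatError(f"sidecar missing required field 'pixel_mm': {sidecar}")
        if "frame_times_ms" not in meta:
            raise SeriesFormatError(f"sidecar missing required field 'frame_times_ms': {sidecar}")
        pixel_mm = float(meta["pixel_mm"])
        frame_times = np.asarray(meta["frame_times_ms"], dtype=float)
        if hdr_pixel > 0 and abs(hdr_pixel - pixel_mm) > 1e-6:
            warnings.warn(
                f"pixel size conflict: header {hdr_pixel} mm vs sidecar {pixel_mm} mm; "
                "sidecar wins",
                stacklevel=2,
            )
        kind = meta.get("kind", "cine")
        if kind == "velocity":
            return VelocitySeries(
                frames=frames,
                venc=float(meta["venc_mm_per_ms"]),
                pixel_mm=pixel_mm,
                frame_times=frame_times,
                plane=meta.get("plane", ""),
                provenance=meta.get("provenance", {}),
            )
        return CineSeries(
            frames=frames,
            pixel_mm=pixel_mm,
            frame_times=frame_times,
            plane=meta.get("plane", ""),
            provenance=meta.get("provenance", {}),
        )

    # header-only NIfTI
    if hdr_dt <= 0:
        raise SeriesFormatError(
            f"{path.name}: temporal spacing missing from NIfTI header and no sidecar present"
        )
    frame_times = np.arange(frames.shape[0], dtype=float) * hdr_dt
    return CineSeries(frames=frames, pixel_mm=hdr_pixel, frame_times=frame_times)
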