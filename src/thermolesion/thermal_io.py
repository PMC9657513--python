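"""Radiometric frame I/O and sensor-count calibration.

A *radiometric* thermal frame is a 2-D raster of absolute skin
temperatures in degrees Celsius.  Three on-disk representations are
supported:

``.csv``
    Plain numeric matrix of temperatures in °C; ``nan`` marks invalid
    pixels (hair, dropouts).
``.tif`` / ``.tiff``
    16-bit grayscale, pixel value = temperature / 0.01 °C (centi-degree
    convention common to radiometric LWIR cameras).  A stored value of 0
    marks an invalid pixel.  Quantisation error is at most 0.005 °C.
``.npy``
    Native float64 array (lossless), with acquisition metadata in a JSON
    sidecar ``<path>.json``.

Acquisition geometry (sensor-to-lesion distance *d*, focal length *f*,
physical pixel pitch *W* × *L*) travels with the frame; it is needed only
when pixel areas are converted to cm².
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import CalibrationError, FrameIOError

#: TIFF encoding scale, °C per stored 16-bit unit.
TIFF_SCALE = 0.01

#: Physical plausibility bounds for a skin-scene temperature, °C.
TEMP_MIN, TEMP_MAX = -20.0, 60.0

_SIDECAR_KEYS = {
    "distance_cm": "distance_d",
    "focal_cm": "focal_f",
    "pixel_w_cm": "pixel_width_w",
    "pixel_l_cm": "pixel_length_l",
    "session_id": "session_id",
    "timestamp": "timestamp",
}


@dataclass
class ThermalFrame:
    """Calibrated 2-D temperature raster with acquisition geometry.

    Parameters
    ----------
    grid
        Temperatures in °C, shape ``(height, width)``.
    mask
        Boolean validity mask, same shape; ``True`` where the pixel holds
        a trustworthy temperature.
    distance_d, focal_f
        Sensor-to-lesion distance and optical focal length, cm.
    pixel_width_w, pixel_length_l
        Physical pixel pitch on the sensor, cm.
    """

    grid: np.ndarray
    mask: np.ndarray | None = None
    distance_d: float | None = None
    focal_f: float | None = None
    pixel_width_w: float | None = None
    pixel_length_l: float | None = None
    session_id: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or 0 in self.grid.shape:
            raise ValueError(f"grid must be a non-empty 2-D array, got shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.isfinite(self.grid)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match grid shape")
        self.mask &= np.isfinite(self.grid)
        valid = self.grid[self.mask]
        if valid.size and (valid.min() < TEMP_MIN or valid.max() > TEMP_MAX):
            raise ValueError(
                f"valid temperatures outside plausible range [{TEMP_MIN}, {TEMP_MAX}] °C"
            )
        for name in ("distance_d", "focal_f"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_temperatures(self) -> np.ndarray:
        """1-D array of temperatures at valid pixels."""
        return self.grid[self.mask]

    def copy(self) -> "ThermalFrame":
        return dataclasses.replace(self, grid=self.grid.copy(), mask=self.mask.copy())

    def metadata(self) -> dict:
        """Acquisition metadata as a plain dict (sidecar key names)."""
        return {
            "distance_cm": self.distance_d,
            "focal_cm": self.focal_f,
            "pixel_w_cm": self.pixel_width_w,
            "pixel_l_cm": self.pixel_length_l,
            "session_id": self.session_id,
            "timestamp": self.timestamp,
        }


@dataclass
class RawFrame:
    """Uncalibrated sensor counts with the same geometry metadata."""

    counts: np.ndarray
    distance_d: float | None = None
    focal_f: float | None = None
    pixel_width_w: float | None = None
    pixel_length_l: float | None = None
    session_id: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or 0 in self.counts.shape:
            raise ValueError("counts must be a non-empty 2-D array")
        if np.any(self.counts < 0):
            raise ValueError("sensor counts must be non-negative")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear count-to-temperature model ``T = gain_a * counts + offset_b``."""

    gain_a: float
    offset_b: float

    def __post_init__(self) -> None:
        if not self.gain_a > 0:
            raise ValueError("gain_a must be positive")

    def apply(self, counts: np.ndarray) -> np.ndarray:
        return self.gain_a * np.asarray(counts, dtype=float) + self.offset_b


def _metadata_kwargs(metadata: Mapping | None) -> dict:
    if not metadata:
        return {}
    out = {}
    for key, val in metadata.items():
        out[_SIDECAR_KEYS.get(key, key)] = val
    return out


def read_frame(path: str | Path, metadata: Mapping | None = None) -> ThermalFrame:
    """Read a thermal frame from CSV, 16-bit TIFF, or native ``.npy``.

    ``metadata`` (either field names or sidecar key names such as
    ``distance_cm``) overrides anything found in a sidecar file.
    Non-finite cells are marked invalid.
    """
    path = Path(path)
    if not path.exists():
        raise FrameIOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    meta: dict = {}
    try:
        if suffix == ".csv":
            try:
                grid = np.loadtxt(path, delimiter=",", ndmin=2)
            except ValueError as exc:
                raise FrameIOError(f"non-rectangular or non-numeric CSV: {path}") from exc
        elif suffix in (".tif", ".tiff"):
            raw = tifffile.imread(path)
            if raw.ndim != 2:
                raise FrameIOError(f"expected a single 2-D page in {path}")
            grid = raw.astype(float) * TIFF_SCALE
            grid[raw == 0] = np.nan  # 0 counts = invalid sentinel
        elif suffix == ".npy":
            grid = np.load(path)
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                meta.update(json.loads(sidecar.read_text()))
        else:
            raise FrameIOError(f"unknown frame format {suffix!r} (expect .csv, .tif(f), .npy)")
    except OSError as exc:
        if isinstance(exc, FrameIOError):
            raise
        raise FrameIOError(f"cannot read {path}: {exc}") from exc
    meta.update(dict(metadata) if metadata else {})
    try:
        return ThermalFrame(grid=np.asarray(grid, dtype=float), **_metadata_kwargs(meta))
    except ValueError as exc:
        raise FrameIOError(f"invalid frame in {path}: {exc}") from exc


def write_frame(frame: ThermalFrame, path: str | Path, format: str | None = None) -> None:
    """Write a frame to disk; format inferred from the extension if omitted.

    Invalid pixels are stored as ``nan`` (CSV, npy) or 0 (TIFF).  The npy
    format additionally writes a JSON metadata sidecar and round-trips
    valid pixels bit-for-bit; TIFF quantises to 0.01 °C.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    grid = np.where(frame.mask, frame.grid, np.nan)
    try:
        if fmt == "csv":
            np.savetxt(path, grid, delimiter=",", fmt="%.6f")
        elif fmt in ("tif", "tiff"):
            counts = np.where(
                frame.mask, np.clip(np.round(frame.grid / TIFF_SCALE), 1, 65535), 0
            ).astype(np.uint16)
            tifffile.imwrite(path, counts)
        elif fmt == "npy":
            np.save(path, grid)
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(frame.metadata(), indent=1))
        else:
            raise FrameIOError(f"unknown frame format {fmt!r}")
    except OSError as exc:
        if isinstance(exc, FrameIOError):
            raise
        raise FrameIOError(f"cannot write {path}: {exc}") from exc


def calibrate(
    raw: RawFrame,
    references: Sequence[tuple[np.ndarray, float]],
    default_gain: float = 0.01,
) -> ThermalFrame:
    """Calibrate sensor counts to °C against reference thermometer readings.

    Each reference is ``(region, known_temp)`` where ``region`` is a
    boolean mask over the frame (the patch the reference thermometer
    measured).  With two references the linear model ``T = a·counts + b``
    is solved through the two (mean counts, temperature) pairs; with one
    reference the gain is fixed at ``default_gain`` (°C/count) and only
    the offset is fitted.  The fit is exact at the reference regions.
    """
    if not 1 <= len(references) <= 2:
        raise CalibrationError("calibration needs 1 or 2 reference regions")
    pairs = []
    for region, temp in references:
        region = np.asarray(region, dtype=bool)
        if region.shape != raw.counts.shape:
            raise CalibrationError("reference region shape must match the frame")
        if not region.any():
            raise CalibrationError("reference region is empty")
        pairs.append((float(raw.counts[region].mean()), float(temp)))

    if len(pairs) == 2:
        (c1, t1), (c2, t2) = pairs
        if c1 == c2:
            raise CalibrationError(
                "reference regions have identical mean counts; linear fit is singular"
            )
        gain = (t2 - t1) / (c2 - c1)
        if gain <= 0:
            raise CalibrationError("fitted gain is non-positive; check reference ordering")
        model = CalibrationModel(gain_a=gain, offset_b=t1 - gain * c1)
    else:
        (c1, t1) = pairs[0]
        model = CalibrationModel(gain_a=default_gain, offset_b=t1 - default_gain * c1)

    grid = model.apply(raw.counts)
    return ThermalFrame(
        grid=grid,
        distance_d=raw.distance_d,
        focal_f=raw.focal_f,
        pixel_width_w=raw.pixel_width_w,
        pixel_length_l=raw.pixel_length_l,
        session_id=raw.session_id,
        timestamp=raw.timestamp,
    )
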