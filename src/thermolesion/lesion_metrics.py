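"""Per-session lesion temperature statistics.

The clinically tracked quantity is the temperature contrast

    delta_t = T_core - T_surround   [°C]

between the lesion and the surrounding healthy skin, measured once per
session.  The lesion *core* is the region enclosed by the chosen
boundary isotherm (mean over interior pixels by default; the hottest
interior pixel with ``core="peak"``).  The *surround* is a ring of skin
pixels just outside the boundary — within ``ring_px`` of the polygon,
outside it, and inside the segmented skin mask, so hair and background
never contaminate the reference.

A sensed contrast smaller than the camera's temperature resolution
(0.1 °C for the LWIR microbolometer class targeted here) is classified
as *null*: the sensor cannot distinguish it from zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import shapely

from .errors import MeasurementError
from .isotherm import IsothermContour, absolute_area, extract_contours, lesion_boundary, shoelace_area
from .segmentation import DEFAULT_FLOOR, SkinMask, threshold_frame
from .thermal_io import ThermalFrame

#: Smallest temperature difference the sensor can resolve, °C.
SENSOR_RESOLUTION = 0.1

#: Default surround-ring width, pixels.
DEFAULT_RING_PX = 10


class Variation(str, enum.Enum):
    """Sign classification of a temperature difference at sensor resolution."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NULL = "null"


@dataclass
class LesionMeasurement:
    """One session's lesion record: core/surround temperatures and areas."""

    session_id: str
    core_temp: float
    surround_temp: float
    delta_t: float
    area_px: float
    area_cm2: float | None
    boundary_level: float
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.delta_t, self.core_temp - self.surround_temp):
            raise ValueError("delta_t must equal core_temp - surround_temp")
        if self.area_px < 0:
            raise ValueError("area_px must be non-negative")


def _polygon(boundary: IsothermContour) -> shapely.Polygon:
    poly = shapely.Polygon(boundary.vertices)
    if poly.area == 0:
        raise MeasurementError("boundary polygon is degenerate (zero area)")
    return poly


def _pixel_centers(frame: ThermalFrame) -> tuple[np.ndarray, np.ndarray]:
    xx, yy = np.meshgrid(np.arange(frame.width), np.arange(frame.height))
    return xx.astype(float), yy.astype(float)


def core_temperature(
    frame: ThermalFrame, boundary: IsothermContour, core: str = "mean"
) -> float:
    """Lesion-core temperature inside the boundary isotherm.

    Pixels whose centers fall strictly inside the polygon count;
    on-edge pixels are excluded (deterministic point-in-polygon).
    ``core="mean"`` averages them, ``core="peak"`` takes the hottest.
    """
    if core not in ("mean", "peak"):
        raise ValueError(f"core must be 'mean' or 'peak', got {core!r}")
    poly = _polygon(boundary)
    xx, yy = _pixel_centers(frame)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(frame.grid.shape)
    inside &= frame.mask
    if not inside.any():
        raise MeasurementError("no valid pixel centers strictly inside the boundary")
    temps = frame.grid[inside]
    return float(temps.max() if core == "peak" else temps.mean())


def surround_temperature(
    frame: ThermalFrame,
    boundary: IsothermContour,
    skin: SkinMask,
    ring_px: int = DEFAULT_RING_PX,
) -> float:
    """Mean temperature of healthy skin in a ring just outside the boundary.

    Ring pixels are within ``ring_px`` of the boundary polygon, outside
    it, valid, and inside the skin mask.
    """
    if ring_px < 1:
        raise ValueError("ring_px must be >= 1")
    if skin.mask.shape != frame.grid.shape:
        raise MeasurementError("skin mask shape must match the frame")
    poly = _polygon(boundary)
    grown = poly.buffer(float(ring_px))
    xx, yy = _pixel_centers(frame)
    pts_x, pts_y = xx.ravel(), yy.ravel()
    in_ring = shapely.contains_xy(grown, pts_x, pts_y) & ~shapely.contains_xy(
        poly, pts_x, pts_y
    )
    ring = in_ring.reshape(frame.grid.shape) & frame.mask & skin.mask
    # drop pixels sitting exactly on the boundary polygon itself
    on_edge = shapely.intersects_xy(poly.exterior, pts_x, pts_y).reshape(frame.grid.shape)
    ring &= ~on_edge
    if not ring.any():
        raise MeasurementError(
            "empty surround ring: the lesion fills the skin region or touches the border"
        )
    return float(frame.grid[ring].mean())


def classify_variation(delta_t: float, resolution: float = SENSOR_RESOLUTION) -> Variation:
    """Classify a temperature difference as positive/negative/null.

    Differences smaller in magnitude than the sensor resolution are
    indistinguishable from zero and classified *null*.
    """
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    if abs(delta_t) < resolution:
        return Variation.NULL
    return Variation.POSITIVE if delta_t > 0 else Variation.NEGATIVE


def measure(
    frame: ThermalFrame,
    boundary_level: float,
    skin: SkinMask | None = None,
    ring_px: int = DEFAULT_RING_PX,
    core: str = "mean",
    eq3_as_printed: bool = False,
) -> LesionMeasurement:
    """Full per-session measurement at a fixed boundary isotherm level.

    If no skin mask is supplied, the body mask (valid pixels at or above
    the 34 °C background floor) is used, so the surround ring averages
    over healthy skin rather than only the Otsu-selected warmest class.
    Extracts the boundary contour at ``boundary_level`` and assembles
    core temperature, surround temperature, their difference, and the
    enclosed area in pixel² (and cm² when acquisition geometry is
    present).
    """
    if skin is None:
        skin = threshold_frame(frame, DEFAULT_FLOOR)
    contours = extract_contours(frame, [boundary_level])
    boundary = lesion_boundary(contours, boundary_level)
    t_core = core_temperature(frame, boundary, core=core)
    t_surround = surround_temperature(frame, boundary, skin, ring_px=ring_px)
    area_px = shoelace_area(boundary)
    geometry = (frame.distance_d, frame.focal_f, frame.pixel_width_w, frame.pixel_length_l)
    area_cm2 = (
        absolute_area(area_px, frame, eq3_as_printed=eq3_as_printed)
        if None not in geometry
        else None
    )
    return LesionMeasurement(
        session_id=frame.session_id or "",
        core_temp=t_core,
        surround_temp=t_surround,
        delta_t=t_core - t_surround,
        area_px=area_px,
        area_cm2=area_cm2,
        boundary_level=float(boundary_level),
        timestamp=frame.timestamp,
    )
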