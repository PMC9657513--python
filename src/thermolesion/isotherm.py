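"""Isotherm contour lines and lesion areas.

A hemangioma shows up as a set of nested, closed temperature contour
lines; the hotter the level, the smaller the enclosed region.  Contours
are traced by marching squares with linear interpolation between pixel
centers (sub-pixel accuracy), the enclosed area comes from the classic
coordinate (shoelace) method

    S1 = sum_i x_i * y_{i+1},   S2 = sum_i x_{i+1} * y_i,
    A  = |S1 - S2| / 2          [pixel^2]

with the closing vertex duplicated, and pixel area is converted to cm²
through the pinhole-camera magnification

    A_abs = A * (d / f)^2 * W * L

where *d* is the lesion-to-sensor distance, *f* the focal length and
*W*, *L* the physical pixel pitch.  (An alternative convention with the
reciprocal ``(f/d)**2`` factor appears in some system descriptions; it is
available behind the ``eq3_as_printed`` flag but shrinks rather than
magnifies the image-plane area for d >> f, so the pinhole form is the
default.)

Coordinates are ``(x, y)`` = (column, row), origin at the top-left pixel
center.  Contour chains that run off the image (or the valid-pixel
region) are closed along the border and flagged ``touches_border``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import ContourError
from .thermal_io import ThermalFrame

#: Default isotherm range, °C: the band in which skin temperature varies
#: in the presence of a vascular anomaly.
DEFAULT_LEVEL_RANGE = (35.5, 38.0)

#: Default number of contour levels drawn across the range.
DEFAULT_N_LEVELS = 6

# Sentinel poured into invalid / padded cells before marching squares;
# far below any physiological level so every contour closes.
_FILL = -1000.0


def default_levels(
    low: float = DEFAULT_LEVEL_RANGE[0],
    high: float = DEFAULT_LEVEL_RANGE[1],
    n: int = DEFAULT_N_LEVELS,
) -> np.ndarray:
    """``n`` equally spaced contour levels spanning ``[low, high]`` °C."""
    return np.linspace(low, high, n)


@dataclass
class IsothermContour:
    """A closed contour at a fixed temperature level.

    ``vertices`` is a ``(k, 2)`` array of ``(x, y)`` sub-pixel
    coordinates whose first row is repeated as the last (the closing
    vertex counts twice, as the coordinate method requires).
    """

    level: float
    vertices: np.ndarray
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be a (k, 2) array of (x, y) pairs")
        if len(self.vertices) < 4:
            raise ValueError("a closed contour needs >= 4 vertices including the duplicate")
        if not np.allclose(self.vertices[0], self.vertices[-1]):
            raise ValueError("contour must be closed: first vertex must equal last")

    @property
    def is_closed(self) -> bool:
        return True

    def centroid(self) -> tuple[float, float]:
        """(x, y) mean of the distinct vertices."""
        pts = self.vertices[:-1]
        return float(pts[:, 0].mean()), float(pts[:, 1].mean())


@dataclass
class ContourSet:
    """All contours extracted from one frame at the requested levels."""

    contours: list[IsothermContour] = field(default_factory=list)
    levels: np.ndarray = field(default_factory=lambda: np.array([]))

    def at_level(self, level: float, atol: float = 1e-9) -> list[IsothermContour]:
        return [c for c in self.contours if abs(c.level - level) <= atol]


def extract_contours(frame: ThermalFrame, levels=None) -> ContourSet:
    """Trace isotherms at each level by marching squares.

    Invalid pixels and a one-pixel pad around the image are filled with a
    deep-cold sentinel first, so every chain closes; chains forced shut
    along the image or mask border are flagged ``touches_border``.  A
    level outside the observed temperature range simply yields no
    contours.
    """
    if frame.height < 2 or frame.width < 2:
        raise ContourError("frame must be at least 2x2 pixels for contour extraction")
    if levels is None:
        levels = default_levels()
    levels = np.atleast_1d(np.asarray(levels, dtype=float))

    filled = np.where(frame.mask, frame.grid, _FILL)
    padded = np.pad(filled, 1, constant_values=_FILL)
    h, w = frame.height, frame.width

    out: list[IsothermContour] = []
    for level in levels:
        for chain in measure.find_contours(padded, level):
            # chain is (row, col) in padded coordinates; shift back
            y = chain[:, 0] - 1.0
            x = chain[:, 1] - 1.0
            touches = bool(
                (x < 0).any() or (y < 0).any() or (x > w - 1).any() or (y > h - 1).any()
            )
            if touches:
                x = np.clip(x, 0.0, w - 1.0)
                y = np.clip(y, 0.0, h - 1.0)
            verts = np.column_stack([x, y])
            if not np.allclose(verts[0], verts[-1]):
                verts = np.vstack([verts, verts[:1]])
            if len(verts) < 4:
                continue
            out.append(IsothermContour(level=float(level), vertices=verts, touches_border=touches))
    return ContourSet(contours=out, levels=levels)


def shoelace_area(contour: IsothermContour | np.ndarray) -> float:
    """Enclosed area of a closed polygon by the coordinate method, pixel².

    Orientation-independent (absolute value) and invariant to the choice
    of starting vertex.  Requires the closing vertex to be duplicated and
    at least three distinct vertices.
    """
    verts = contour.vertices if isinstance(contour, IsothermContour) else np.asarray(contour, float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 4:
        raise ContourError("need a closed polygon: (k, 2) vertices with k >= 4")
    if not np.allclose(verts[0], verts[-1]):
        raise ContourError("polygon is not closed (first vertex != last)")
    distinct = np.unique(verts[:-1], axis=0)
    if len(distinct) < 3:
        raise ContourError("polygon needs at least 3 distinct vertices")
    x, y = verts[:, 0], verts[:, 1]
    s1 = float(np.dot(x[:-1], y[1:]))
    s2 = float(np.dot(x[1:], y[:-1]))
    return abs(s1 - s2) / 2.0


def absolute_area(
    area_px: float, frame: ThermalFrame, eq3_as_printed: bool = False
) -> float:
    """Convert a pixel-unit area to cm² using the frame's geometry.

    Default: ``A_abs = area_px * (d/f)**2 * W * L`` (object-plane
    magnification of the image-plane pixel footprint).  With
    ``eq3_as_printed=True`` the reciprocal ``(f/d)**2`` factor is used
    instead.  The two coincide when ``d == f``.
    """
    if area_px < 0:
        raise ValueError("area_px must be non-negative")
    d, f = frame.distance_d, frame.focal_f
    w, l = frame.pixel_width_w, frame.pixel_length_l
    if None in (d, f, w, l):
        raise ContourError(
            "absolute area needs distance_d, focal_f, pixel_width_w and pixel_length_l"
        )
    mag = (f / d) ** 2 if eq3_as_printed else (d / f) ** 2
    return float(area_px) * mag * w * l


def lesion_boundary(contours: ContourSet, level: float) -> IsothermContour:
    """The lesion-delimiting contour: largest-area closed contour at ``level``.

    The same level reused across clinical sessions makes the enclosed
    areas comparable.  Contours closed without touching the border are
    preferred over border-truncated ones; ties are broken
    deterministically toward the smallest centroid (row, then column).
    """
    candidates = contours.at_level(level)
    interior = [c for c in candidates if not c.touches_border]
    if interior:
        candidates = interior
    if not candidates:
        raise ContourError(f"no closed contour at level {level} °C")

    def key(c: IsothermContour):
        cx, cy = c.centroid()
        return (-shoelace_area(c), cy, cx)

    return min(candidates, key=key)
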