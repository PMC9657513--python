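"""Skin segmentation on the temperature histogram.

The scene in a bedside thermogram has up to four temperature modes:
image background (coolest), hair, healthy skin, and the lesion (warmest,
because a hemangioma's increased blood flow heats the overlying skin).
Segmentation proceeds in four steps:

1. histogram the valid temperatures,
2. discard everything below a pre-filter floor (default 34 °C) so inert
   background objects no longer dominate the histogram,
3. find the optimal threshold *TH* by Otsu's criterion — maximising the
   between-class variance ``w0*w1*(mu0 - mu1)**2`` over candidate bin
   edges,
4. keep pixels at or above *TH*.

Removed pixels are marked invalid in the frame's validity mask rather
than being zeroed, so downstream temperature statistics never see
sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SegmentationError
from .thermal_io import ThermalFrame

#: Default histogram bin width, °C: half the sensor's 0.1 °C resolution.
DEFAULT_BIN_WIDTH = 0.05

#: Default background pre-filter floor, °C (temperatures below are not
#: compatible with body temperature).
DEFAULT_FLOOR = 34.0


@dataclass(frozen=True)
class TemperatureHistogram:
    """Binned temperature counts.

    ``bin_edges`` has one more element than ``counts``; bins are
    left-closed, the last bin right-closed, so every histogrammed pixel
    lands in exactly one bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1-D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_nonempty(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SkinMask:
    """Boolean skin mask plus the Otsu threshold *TH* that produced it."""

    mask: np.ndarray
    threshold_th: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_skin_pixels(self) -> int:
        return int(self.mask.sum())


def compute_histogram(frame: ThermalFrame, bin_width: float = DEFAULT_BIN_WIDTH) -> TemperatureHistogram:
    """Histogram the frame's valid temperatures at fixed bin width.

    Edges start at the coldest valid temperature and extend in
    ``bin_width`` steps until the hottest is covered; the total count
    equals the number of valid pixels.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    temps = frame.valid_temperatures()
    if temps.size == 0:
        raise SegmentationError("frame has no valid pixels to histogram")
    tmin, tmax = float(temps.min()), float(temps.max())
    # edges start at the minimum and extend in bin_width steps past the
    # maximum, so equal-width populations land in distinct bins
    n_bins = int(np.floor((tmax - tmin) / bin_width + 1e-12)) + 1
    edges = tmin + bin_width * np.arange(n_bins + 1)
    # np.histogram treats the last bin as right-closed, matching the contract
    counts, _ = np.histogram(temps, bins=edges)
    return TemperatureHistogram(bin_edges=edges, counts=counts)


def prefilter_background(frame: ThermalFrame, floor: float = DEFAULT_FLOOR) -> ThermalFrame:
    """Invalidate every pixel colder than ``floor`` (default 34 °C).

    Background objects, clothes and hair sit well below body
    temperature; removing them restores the approximate bimodality that
    Otsu's criterion assumes.  Returns a copy; valid pixels are unchanged.
    """
    if not np.isfinite(floor):
        raise ValueError("floor must be finite")
    out = frame.copy()
    with np.errstate(invalid="ignore"):
        out.mask &= ~(out.grid < floor)
    return out


def otsu_threshold(hist: TemperatureHistogram) -> float:
    """Optimal threshold *TH* by Otsu's between-class variance criterion.

    Every interior bin edge is a candidate split: class 0 holds the bins
    strictly below the edge, class 1 the rest.  The returned *TH* is the
    edge maximising ``w0*w1*(mu0 - mu1)**2`` with bin centers as class
    values; ties are broken toward the lowest threshold (keeping the most
    skin).  Needs at least two non-empty bins.
    """
    if hist.n_nonempty < 2:
        raise SegmentationError(
            "Otsu needs at least two non-empty histogram bins (no bimodality possible)"
        )
    counts = hist.counts.astype(float)
    centers = hist.bin_centers
    total = counts.sum()

    # cumulative class weight and mean below each interior edge
    w0 = np.cumsum(counts)[:-1] / total
    w1 = 1.0 - w0
    cum_mass = np.cumsum(counts * centers)
    mu0 = np.divide(cum_mass[:-1], w0 * total, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(
        cum_mass[-1] - cum_mass[:-1], w1 * total, out=np.zeros_like(w1), where=w1 > 0
    )
    between = w0 * w1 * (mu0 - mu1) ** 2
    # candidate k corresponds to edge k+1; first index wins a tie (lowest TH)
    best = int(np.flatnonzero(np.isclose(between, between.max(), rtol=1e-12, atol=0.0))[0])
    return float(hist.bin_edges[best + 1])


def threshold_frame(frame: ThermalFrame, th: float) -> SkinMask:
    """Mask of valid pixels with temperature >= ``th``."""
    with np.errstate(invalid="ignore"):
        mask = frame.mask & (frame.grid >= th)
    return SkinMask(mask=mask, threshold_th=float(th))


def segment_skin(
    frame: ThermalFrame,
    floor: float = DEFAULT_FLOOR,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> SkinMask:
    """Full four-step segmentation: pre-filter, histogram, Otsu, threshold."""
    filtered = prefilter_background(frame, floor=floor)
    if filtered.n_valid == 0:
        raise SegmentationError(f"no pixels at or above the {floor} °C pre-filter floor")
    hist = compute_histogram(filtered, bin_width=bin_width)
    th = otsu_threshold(hist)
    return threshold_frame(filtered, th)
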