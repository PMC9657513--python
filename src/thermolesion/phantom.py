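"""Synthetic thermal phantoms with analytic ground truth.

A phantom scene mimics the four temperature modes of a bedside
thermogram: a cool background (default 25 °C), a skin region at body
surface temperature (default 36.2 °C), zero or more warm lesions, and
optional hair-like occlusion (sub-34 °C speckle that the background
pre-filter removes).  Each lesion is a radial Gaussian bump

    T(r) = T_skin + A * exp(-r**2 / (2 * sigma**2)),

the minimal smooth profile producing the nested-isotherm structure seen
over a hemangioma.  Its isotherm at level ``T_iso`` (with
``T_skin < T_iso < T_skin + A``) is the circle of radius
``rho = sigma * sqrt(2 * ln(A / (T_iso - T_skin)))``, so the enclosed
area has the closed form

    area(T_iso) = pi * 2 * sigma**2 * ln(A / (T_iso - T_skin)),

which every pipeline stage can be checked against.  Additive Gaussian
sensor noise (default sd 0.05 °C, half the 0.1 °C sensor resolution) is
applied inside the skin region only; a fixed seed reproduces the frame
bit-for-bit.

Treatment time courses are emulated by scaling each lesion's amplitude
and width per session: shrinking scales model involution under therapy,
growing scales model regrowth after discontinuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .thermal_io import ThermalFrame

#: Default phantom acquisition geometry: 30 cm working distance with a
#: small LWIR module (focal length ~1 mm, 12 um pixel pitch).
DEFAULT_GEOMETRY = {
    "distance_d": 30.0,
    "focal_f": 0.095,
    "pixel_width_w": 0.0012,
    "pixel_length_l": 0.0012,
}

_HAIR_RANGE = (30.0, 33.9)


@dataclass(frozen=True)
class GaussianLesion:
    """Radial Gaussian warm spot: center (x, y), width sigma, amplitude in °C."""

    x: float
    y: float
    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")

    def iso_radius(self, level: float, t_skin: float) -> float:
        """Radius of the isotherm at ``level`` °C (0 if level is out of range)."""
        excess = level - t_skin
        if not 0 < excess < self.amplitude:
            return 0.0
        return self.sigma * math.sqrt(2.0 * math.log(self.amplitude / excess))

    def iso_area(self, level: float, t_skin: float) -> float:
        """Analytic isotherm-enclosed area, pixel²."""
        excess = level - t_skin
        if not 0 < excess < self.amplitude:
            return 0.0
        return math.pi * 2.0 * self.sigma**2 * math.log(self.amplitude / excess)

    def mean_core_excess(self, level: float, t_skin: float) -> float:
        """Mean temperature excess over the disk enclosed by the ``level`` isotherm.

        The disk mean of ``A*exp(-r^2/(2 sigma^2))`` over radius rho is
        ``A * (2 sigma^2 / rho^2) * (1 - exp(-rho^2 / (2 sigma^2)))``.
        """
        rho = self.iso_radius(level, t_skin)
        if rho == 0.0:
            return 0.0
        u = rho**2 / (2.0 * self.sigma**2)
        return self.amplitude * (1.0 - math.exp(-u)) / u


@dataclass(frozen=True)
class SkinRegion:
    """Rectangle or ellipse delimiting skin within the frame.

    ``shape="rect"``: cx, cy are the top-left corner and rx, ry the full
    width/height.  ``shape="ellipse"``: cx, cy the center and rx, ry the
    semi-axes.
    """

    shape: str
    cx: float
    cy: float
    rx: float
    ry: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.shape == "rect":
            return (
                (x >= self.cx) & (x < self.cx + self.rx)
                & (y >= self.cy) & (y < self.cy + self.ry)
            )
        if self.shape == "ellipse":
            return ((x - self.cx) / self.rx) ** 2 + ((y - self.cy) / self.ry) ** 2 <= 1.0
        raise ValueError(f"unknown skin region shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic scene."""

    height: int = 160
    width: int = 160
    t_bg: float = 25.0
    t_skin: float = 36.2
    skin_region: SkinRegion | None = None
    lesions: tuple[GaussianLesion, ...] = ()
    hair_occlusion_frac: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("phantom must be at least 2x2 pixels")
        if not self.t_bg < 34.0 <= self.t_skin:
            raise ValueError("need t_bg < 34 <= t_skin so the pre-filter separates them")
        if not 0.0 <= self.hair_occlusion_frac < 1.0:
            raise ValueError("hair_occlusion_frac must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    def region(self) -> SkinRegion:
        """The skin region, defaulting to the full frame."""
        return self.skin_region or SkinRegion("rect", 0, 0, self.width, self.height)


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a generated phantom."""

    t_skin: float
    t_bg: float
    lesions: tuple[GaussianLesion, ...]
    labels: np.ndarray  # 0 = background, 1 = skin, 2 = hair occlusion

    def iso_area(self, level: float, lesion: int = 0) -> float:
        return self.lesions[lesion].iso_area(level, self.t_skin)

    def iso_radius(self, level: float, lesion: int = 0) -> float:
        return self.lesions[lesion].iso_radius(level, self.t_skin)

    def delta_t(self, level: float, lesion: int = 0, core: str = "mean") -> float:
        """True lesion-vs-skin contrast at the given boundary level.

        The surround reference is the noiseless skin temperature; the
        core is either the disk-mean excess (``core="mean"``) or the
        peak amplitude (``core="peak"``).
        """
        les = self.lesions[lesion]
        if core == "peak":
            return les.amplitude
        return les.mean_core_excess(level, self.t_skin)


def generate_phantom(
    spec: PhantomSpec, session_id: str = "phantom", timestamp: str | None = None
) -> tuple[ThermalFrame, PhantomTruth]:
    """Render a phantom scene to a ThermalFrame with its ground truth.

    Deterministic for a fixed spec (including seed).  Lesion centers must
    lie inside the skin region.
    """
    region = spec.region()
    xx, yy = np.meshgrid(
        np.arange(spec.width, dtype=float), np.arange(spec.height, dtype=float)
    )
    skin = region.contains(xx, yy)
    for les in spec.lesions:
        if not region.contains(np.array([les.x]), np.array([les.y]))[0]:
            raise ValueError(f"lesion at ({les.x}, {les.y}) lies outside the skin region")

    grid = np.full((spec.height, spec.width), spec.t_bg, dtype=float)
    temp_skin = np.full_like(grid, spec.t_skin)
    for les in spec.lesions:
        r2 = (xx - les.x) ** 2 + (yy - les.y) ** 2
        temp_skin += les.amplitude * np.exp(-r2 / (2.0 * les.sigma**2))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        temp_skin = temp_skin + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    grid[skin] = temp_skin[skin]

    labels = skin.astype(np.uint8)
    if spec.hair_occlusion_frac > 0:
        skin_idx = np.flatnonzero(skin.ravel())
        n_hair = int(round(spec.hair_occlusion_frac * skin_idx.size))
        if n_hair:
            chosen = rng.choice(skin_idx, size=n_hair, replace=False)
            hair_temps = rng.uniform(*_HAIR_RANGE, size=n_hair)
            grid.ravel()[chosen] = hair_temps
            labels.ravel()[chosen] = 2

    frame = ThermalFrame(
        grid=grid, session_id=session_id, timestamp=timestamp, **DEFAULT_GEOMETRY
    )
    truth = PhantomTruth(
        t_skin=spec.t_skin, t_bg=spec.t_bg, lesions=spec.lesions, labels=labels
    )
    return frame, truth


def generate_series(
    spec: PhantomSpec,
    response: Sequence[tuple[float, float]] | Sequence[tuple[int, float, float]],
) -> list[tuple[ThermalFrame, PhantomTruth]]:
    """Render a treatment time course: one phantom per session.

    ``response`` is a sequence of per-session ``(amplitude_scale,
    sigma_scale)`` pairs (a leading session index is accepted and
    ignored).  Scales below 1 emulate involution under treatment, above 1
    regrowth after discontinuation.  Session *t* reseeds the noise with
    ``spec.seed + t`` so frames are independent but reproducible.
    """
    out = []
    for t, scales in enumerate(response):
        if len(scales) == 3:
            _, amp_scale, sig_scale = scales
        else:
            amp_scale, sig_scale = scales
        if not (amp_scale > 0 and sig_scale > 0):
            raise ValueError("amplitude and sigma scales must be positive")
        lesions = tuple(
            replace(l, amplitude=l.amplitude * amp_scale, sigma=l.sigma * sig_scale)
            for l in spec.lesions
        )
        session_spec = replace(spec, lesions=lesions, seed=spec.seed + t)
        out.append(
            generate_phantom(session_spec, session_id=f"session-{t}", timestamp=f"{t:04d}")
        )
    return out
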