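"""Run configuration shared by the CLI and the analysis pipeline."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with its default.

    Serialisable to/from a plain dict (and TOML), and echoed verbatim
    into every JSON report so a run can be reproduced from its output.
    """

    floor: float = 34.0               # °C, background pre-filter
    bin_width: float = 0.05           # °C, histogram bin width
    level_low: float = 35.5           # °C, isotherm range start
    level_high: float = 38.0          # °C, isotherm range end
    n_levels: int = 6                 # contour lines across the range
    boundary_level: float = 36.5      # °C, lesion-delimiting isotherm
    ring_px: int = 10                 # surround-ring width, pixels
    core: str = "mean"                # "mean" | "peak" core definition
    resolution: float = 0.1           # °C, sensor temperature resolution
    substantial_frac: float = -0.2    # rule (iii) area-change threshold
    eq3_as_printed: bool = False      # use the (f/d)^2 area convention
    default_gain: float = 0.01        # °C/count, 1-point calibration gain
    seed: int = 0                     # phantom generation seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def levels(self):
        from .isotherm import default_levels

        return default_levels(self.level_low, self.level_high, self.n_levels)
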