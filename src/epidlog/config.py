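"""Pipeline configuration: detector geometry and per-stage parameters.

A single TOML file configures a run; CLI flags override individual fields.
Every run writes its resolved configuration next to its outputs so the run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


class ConfigError(ValueError):
    pass


@dataclass
class DetectorGeometry:
    """Square detector; pixel spacing given projected to the isocenter plane.

    Pixel (r, c) covers the half-open span [r, r+1) x [c, c+1); the beam axis
    crosses the detector at pixel coordinate ((resolution-1)/2,) * 2, i.e. the
    physical center maps to the pixel-boundary coordinate resolution/2.
    """

    resolution: int = 512
    pixel_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.resolution < 16:
            raise ConfigError("detector resolution must be >= 16")
        if self.pixel_mm <= 0:
            raise ConfigError("pixel_mm must be > 0")

    @property
    def center_px(self) -> float:
        """Pixel-index coordinate of the beam axis (for pixel centers)."""
        return (self.resolution - 1) / 2.0

    def boundary_to_mm(self, boundary: float) -> float:
        """Convert a pixel-boundary coordinate to signed mm at isocenter."""
        return (boundary - self.resolution / 2.0) * self.pixel_mm

    def mm_to_boundary(self, mm: float) -> float:
        return mm / self.pixel_mm + self.resolution / 2.0

    def pixel_center_mm(self, index: int) -> float:
        return (index + 0.5 - self.resolution / 2.0) * self.pixel_mm


@dataclass
class DeconvConfig:
    sigma: float = 2.0
    tol: float = 1e-4
    max_iter: int = 50


@dataclass
class ThresholdConfig:
    grid_step: float = 100.0
    tolerance: float = 0.02  # on the 2/3/4 linearity ratios
    band_half_rows: int = 5


@dataclass
class MuConfig:
    stat: str = "mean"  # or "sum"
    angle_map: str = "mu"  # or "time"

    def __post_init__(self) -> None:
        if self.stat not in ("mean", "sum"):
            raise ConfigError(f"mu.stat must be 'mean' or 'sum', got {self.stat!r}")
        if self.angle_map not in ("mu", "time"):
            raise ConfigError(f"mu.angle_map must be 'mu' or 'time', got {self.angle_map!r}")


@dataclass
class ComplexityConfig:
    sas_gap_mm: float = 10.0
    lt_norm_mm: float = 500.0


@dataclass
class GammaConfig:
    dd: float = 3.0
    dta: float = 3.0
    cut: float = 0.10


@dataclass
class PipelineConfig:
    detector: DetectorGeometry = field(default_factory=DetectorGeometry)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    mu: MuConfig = field(default_factory=MuConfig)
    complexity: ComplexityConfig = field(default_factory=ComplexityConfig)
    gamma: GammaConfig = field(default_factory=GammaConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "detector": DetectorGeometry,
            "deconv": DeconvConfig,
            "threshold": ThresholdConfig,
            "mu": MuConfig,
            "complexity": ComplexityConfig,
            "gamma": GammaConfig,
        }
        for key, klass in sections.items():
            if key in data:
                known = {f.name for f in dataclasses.fields(klass)}
                extra = set(data[key]) - known
                if extra:
                    raise ConfigError(f"unknown keys in [{key}]: {sorted(extra)}")
                kwargs[key] = klass(**data[key])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml_text(self) -> str:
        lines = [f"seed = {self.seed}", ""]
        for section, obj in (
            ("detector", self.detector),
            ("deconv", self.deconv),
            ("threshold", self.threshold),
            ("mu", self.mu),
            ("complexity", self.complexity),
            ("gamma", self.gamma),
        ):
            lines.append(f"[{section}]")
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                lines.append(f'{f.name} = "{v}"' if isinstance(v, str) else f"{f.name} = {v}")
            lines.append("")
        return "\n".join(lines)
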