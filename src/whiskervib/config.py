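"""Structured run configuration: YAML parsing, validation and unit handling.

Internal computation is SI throughout; the config file accepts the units
whisker measurements are reported in (mm, um, g/cm^3, GPa) through explicit
unit-suffixed keys, e.g. ``length_mm`` or ``base_radius_um``.
Unknown keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .forcing import ForceProfile
from .geometry import ContactConfig, WhiskerGeometry

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]


@dataclass
class GeometryBlock:
    length_mm: float = 18.0
    base_radius_um: float = 37.0
    truncation_ratio: float = 0.05
    density_g_cm3: float = 1.0
    youngs_modulus_gpa: float = 3.0
    damping_rad_s: float = 430.0

    def build(self) -> WhiskerGeometry:
        L = self.length_mm * 1e-3
        return WhiskerGeometry(
            L=L,
            R=self.base_radius_um * 1e-6,
            trunc=self.truncation_ratio * L,
            rho=self.density_g_cm3 * 1e3,
            E=self.youngs_modulus_gpa * 1e9,
            alpha=self.damping_rad_s,
        )


@dataclass
class ContactBlock:
    c_ratio: float = 0.6

    def build(self, geom: WhiskerGeometry) -> ContactConfig:
        return ContactConfig.from_relative(geom, self.c_ratio)


@dataclass
class ForceBlock:
    kind: str = "gaussian"          # gaussian | ramp
    f_max_un: float = 1.0           # peak force in micronewton
    t_f_ms: float = 10.0
    tau_ms: float = 0.1
    cutoff: float = 0.5
    ramp_slope_n_s: float = 1e-3

    def build(self) -> ForceProfile:
        if self.kind == "gaussian":
            return ForceProfile.gaussian_smooth(
                F_max=self.f_max_un * 1e-6,
                t_f=self.t_f_ms * 1e-3,
                tau=self.tau_ms * 1e-3,
                C=self.cutoff,
            )
        if self.kind == "ramp":
            return ForceProfile.ramp(self.ramp_slope_n_s)
        raise ValueError(f"unknown force kind: {self.kind!r}")


@dataclass
class SolverBlock:
    n_modes: int = 100
    seed: int = 0
    dt_us: float = 10.0


@dataclass
class OutputBlock:
    dir: str = "out"


_BLOCKS = {
    "geometry": GeometryBlock,
    "contact": ContactBlock,
    "force": ForceBlock,
    "solver": SolverBlock,
    "output": OutputBlock,
}


@dataclass
class RunConfig:
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    contact: ContactBlock = field(default_factory=ContactBlock)
    force: ForceBlock = field(default_factory=ForceBlock)
    solver: SolverBlock = field(default_factory=SolverBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    def as_dict(self) -> dict:
        return asdict(self)


def _build_block(cls, data: dict, name: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}; allowed: {sorted(allowed)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}; allowed: {sorted(_BLOCKS)}")
    blocks = {
        name: _build_block(cls, raw.get(name, {}) or {}, name)
        for name, cls in _BLOCKS.items()
    }
    cfg = RunConfig(**blocks)
    # eager validation: building the physical objects checks all invariants
    geom = cfg.geometry.build()
    cfg.contact.build(geom)
    cfg.force.build()
    return cfg


def default_config() -> RunConfig:
    """The standard touch configuration (standard whisker, c/L = 0.6)."""
    return RunConfig()


def config_hash(cfg: RunConfig) -> str:
    """Deterministic short hash of the fully resolved configuration."""
    blob = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
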