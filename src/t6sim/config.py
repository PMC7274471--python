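"""Run configuration: defaults, presets, YAML loading and validation.

Defaults follow the two-strain competition setup used throughout the
simulator: lethal hit threshold ``N_hits = 1``, weapon cost ``c = 0.001``,
and named lysis presets ``slow-lysis`` (k_lysis = 0.8 h^-1) and
``rapid-lysis`` (k_lysis = 8.0 h^-1).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cells import Genotype

__all__ = ["GenotypeConfig", "GrowthConfig", "MechanicsConfig", "RunConfig",
           "load_config", "default_config", "PRESETS"]

PRESETS = {
    "slow-lysis": {"k_lysis": 0.8},
    "rapid-lysis": {"k_lysis": 8.0},
}


class ConfigError(ValueError):
    pass


@dataclass
class GenotypeConfig:
    name: str
    is_attacker: bool = False
    k_fire: float = 0.0                 # firings cell^-1 h^-1
    cost_coeff: float = 0.001           # c
    k_lysis: float = 8.0                # h^-1 (delay delivered to victims)
    n_hits: int = 1                     # N_hits
    growth_rate: float = 0.7            # k_grow, h^-1

    def build(self, gid: int) -> Genotype:
        return Genotype(id=gid, name=self.name, is_attacker=self.is_attacker,
                        k_fire=self.k_fire, cost_coeff=self.cost_coeff,
                        toxin_lysis_rate=self.k_lysis,
                        lethal_hit_threshold=self.n_hits,
                        base_growth_rate=self.growth_rate)


@dataclass
class GrowthConfig:
    division_noise_scale: float | None = None  # um^3; default 0.05 * V0
    orientation_noise_scale: float = 0.05      # rad
    restriction_strength: float = 0.0          # 1/gamma


@dataclass
class MechanicsConfig:
    contact_threshold: float = 0.01
    alpha: float = 1.0
    cg_tolerance: float = 1e-3
    max_resolution_iters: int = 10


@dataclass
class RunConfig:
    arena: str = "disc2d"               # disc2d | biofilm3d | chamber
    seed: int = 0
    dt: float = 0.025                   # h
    snapshot_interval: float = 0.1      # h
    # termination
    population_cap: int = 10000         # disc2d: living + victim count
    duration: float = 13.0              # h; biofilm3d / chamber
    max_hours: float = 48.0             # hard safety cap for disc2d
    # disc2d inoculum
    disc_diameter: float = 100.0        # um
    inoculum_size: int = 100
    attacker_fraction: float = 0.5
    # biofilm3d
    box_base: float = 40.0              # um
    slough_height: float = 20.0         # um
    # chamber
    chamber_length: float = 100.0       # um
    chamber_width: float = 10.0         # um
    burn_in: float = 3.0                # h of growth before t = 0
    # parameter bundles
    genotypes: list[GenotypeConfig] = field(default_factory=lambda: [
        GenotypeConfig(name="attacker", is_attacker=True, k_fire=50.0),
        GenotypeConfig(name="susceptible"),
    ])
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    deterministic_lysis: bool = True
    log_firings: bool = False
    combat_first: bool = True
    output_dir: str | None = None

    def validate(self) -> "RunConfig":
        if self.arena not in ("disc2d", "biofilm3d", "chamber"):
            raise ConfigError(f"arena: unknown arena {self.arena!r}")
        positive = ["dt", "snapshot_interval", "population_cap", "duration",
                    "disc_diameter", "box_base", "slough_height",
                    "chamber_length", "chamber_width"]
        for key in positive:
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key}: must be > 0 (got {getattr(self, key)})")
        if not 0 <= self.attacker_fraction <= 1:
            raise ConfigError("attacker_fraction: must lie in [0, 1]")
        if self.inoculum_size < 1:
            raise ConfigError("inoculum_size: must be >= 1")
        if self.burn_in < 0:
            raise ConfigError("burn_in: must be >= 0")
        for gc in self.genotypes:
            if gc.k_fire < 0:
                raise ConfigError(f"genotypes.{gc.name}.k_fire: must be >= 0")
            if gc.n_hits < 1:
                raise ConfigError(f"genotypes.{gc.name}.n_hits: must be >= 1")
            if gc.k_lysis <= 0:
                raise ConfigError(f"genotypes.{gc.name}.k_lysis: must be > 0")
            if gc.growth_rate < 0:
                raise ConfigError(f"genotypes.{gc.name}.growth_rate: must be >= 0")
            if gc.cost_coeff < 0:
                raise ConfigError(f"genotypes.{gc.name}.cost_coeff: must be >= 0")
        mech = self.mechanics
        if mech.contact_threshold <= 0 or mech.alpha <= 0 or mech.cg_tolerance <= 0:
            raise ConfigError("mechanics: contact_threshold, alpha, cg_tolerance must be > 0")
        gp = self.growth
        if gp.orientation_noise_scale < 0 or gp.restriction_strength < 0 or \
                (gp.division_noise_scale is not None and gp.division_noise_scale < 0):
            raise ConfigError("growth: noise scales and restriction must be >= 0")
        return self

    def build_genotypes(self) -> list[Genotype]:
        return [gc.build(gid) for gid, gc in enumerate(self.genotypes)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _from_dict(cls, data: dict, prefix: str = ""):
    """Build a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{prefix or cls.__name__}: expected a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{prefix or 'top level'}'")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if key == "genotypes":
            if not isinstance(value, list):
                raise ConfigError("genotypes: expected a list")
            kwargs[key] = [_from_dict(GenotypeConfig, v, f"genotypes[{k}]")
                           for k, v in enumerate(value)]
        elif f.type in ("GrowthConfig",) or f.name == "growth":
            kwargs[key] = _from_dict(GrowthConfig, value, "growth")
        elif f.name == "mechanics":
            kwargs[key] = _from_dict(MechanicsConfig, value, "mechanics")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path, preset: str | None = None) -> RunConfig:
    """Load a YAML run configuration, fill defaults, and validate.

    An empty file yields the full default configuration.  Unknown keys are
    rejected (typo safety); out-of-range values raise naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    preset = raw.pop("preset", preset) if isinstance(raw, dict) else preset
    cfg = _from_dict(RunConfig, raw)
    if preset is not None:
        cfg = apply_preset(cfg, preset)
    return cfg.validate()


def apply_preset(cfg: RunConfig, preset: str) -> RunConfig:
    if preset not in PRESETS:
        raise ConfigError(f"preset: unknown preset {preset!r}; "
                          f"choose from {sorted(PRESETS)}")
    for gc in cfg.genotypes:
        if gc.is_attacker:
            gc.k_lysis = PRESETS[preset]["k_lysis"]
    return cfg


def default_config(arena: str = "disc2d", preset: str | None = None,
                   **overrides) -> RunConfig:
    """Programmatic configuration builder used by the CLI and tests."""
    genotype_overrides = {k: overrides.pop(k) for k in
                          ("k_fire", "k_lysis", "n_hits", "cost_coeff",
                           "growth_rate") if k in overrides}
    cfg = _from_dict(RunConfig, dict(overrides, arena=arena))
    if preset is not None:
        cfg = apply_preset(cfg, preset)
    for gc in cfg.genotypes:
        if "growth_rate" in genotype_overrides:
            gc.growth_rate = genotype_overrides["growth_rate"]
        if "n_hits" in genotype_overrides:
            gc.n_hits = genotype_overrides["n_hits"]
        if gc.is_attacker:
            for key in ("k_fire", "k_lysis", "cost_coeff"):
                if key in genotype_overrides:
                    setattr(gc, key, genotype_overrides[key])
    return cfg.validate()


def write_config(cfg: RunConfig, path: str | Path):
    """Persist the fully resolved configuration next to run outputs."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
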