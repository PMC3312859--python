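"""Run configuration: nested dataclasses, YAML round-trip and validation.

Every tunable of the simulator lives here with its default; an empty config
file yields the shipped study conditions (kinetic table defaults, 120×120
high-res lattice nested 6:1, 100 hourly steps, 10 replicates).  Unknown keys
are rejected to catch typos, and out-of-range values are reported with their
dotted config path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .pathway import DEFAULT_INITIAL, KineticParameters

__all__ = ["SimulationConfig", "load_config", "save_config", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; message lists dotted paths."""


@dataclass
class LatticeConfig:
    #: high-resolution lattice extent in nodes (10 μm per node)
    shape: tuple[int, int] = (120, 120)
    #: high-res nodes per low-res cell edge
    nesting: int = 6
    dx_um: float = 10.0


@dataclass
class DiffusionConfig:
    #: chemoattractant diffusivity, cm²/s (small-protein tissue diffusivity)
    diffusivity_cm2_s: float = 1e-7
    #: diffusion sub-steps per ABM step and their length (6 × 600 s = 1 h)
    n_substeps: int = 6
    dt_substep_s: float = 600.0
    boundary: str = "zero-flux"
    secretion_nM_s: float = 0.05
    uptake_rate_per_s: float = 1e-5
    uptake_mode: str = "linear"
    #: optional Schwarz tiling {tile_shape: [h, w], overlap: int, iterations: int}
    schwarz: Optional[dict] = None


@dataclass
class AttractionConfig:
    psi: float = 0.7
    mu: float = 0.0
    sigma: Optional[float] = None  # None -> relative noise
    sigma_rel: float = 0.1
    sigma_min: float = 1e-3


@dataclass
class CycleConfig:
    #: ABM steps between phenotype decisions (one step = one hour)
    decision_interval: int = 12


@dataclass
class OdeConfig:
    #: RK4 micro-step, seconds
    dt_s: float = 0.05
    #: simulated seconds of intracellular dynamics per ABM step
    seconds_per_step: float = 3600.0
    #: "relative" (percentage rate of change of PLCγ-P) or "absolute"
    rate_mode: str = "relative"


@dataclass
class FieldInitConfig:
    kind: str = "gaussian"
    #: peak TGFα concentration of the initial profile, nM
    amplitude_nM: float = 9010.55
    #: Gaussian width as a fraction of the smaller lattice extent
    sigma_frac: float = 0.25
    #: peak location as fractional coordinates of the lattice — the nutrient
    #: source (e.g. a vessel), offset from the tumor so the chemoattractant
    #: gradient crosses the tumor rim
    center_frac: tuple[float, float] = (0.3, 0.3)


@dataclass
class TumorSeedConfig:
    kind: str = "disc"
    radius: int = 5  # high-res nodes


@dataclass
class SimulationConfig:
    steps: int = 100
    seed: int = 0
    replicates: int = 10
    snapshot_every: int = 0  # 0 -> no field/cell snapshots
    #: tissue-to-intracellular TGFα conversion factor (both sides in nM)
    conversion_factor: float = 1.0
    daughter_reset: bool = False
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    initial_pathway: tuple = DEFAULT_INITIAL
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    attraction: AttractionConfig = field(default_factory=AttractionConfig)
    cycle: CycleConfig = field(default_factory=CycleConfig)
    ode: OdeConfig = field(default_factory=OdeConfig)
    field_init: FieldInitConfig = field(default_factory=FieldInitConfig)
    tumor_seed: TumorSeedConfig = field(default_factory=TumorSeedConfig)

    def to_dict(self) -> dict:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)


_TUPLE_FIELDS = {"shape", "center_frac", "initial_pathway"}


def _build(cls, data: dict, path: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    for k in sorted(unknown):
        errors.append(f"{path}{k}: unknown key")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        val = data[name]
        sub = _NESTED.get((cls, name))
        if sub is not None and isinstance(val, dict):
            kwargs[name] = _build(sub, val, f"{path}{name}.", errors)
        elif name in _TUPLE_FIELDS and isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path.rstrip('.') or 'config'}: {exc}")
        return cls()


_NESTED = {
    (SimulationConfig, "lattice"): LatticeConfig,
    (SimulationConfig, "kinetics"): KineticParameters,
    (SimulationConfig, "diffusion"): DiffusionConfig,
    (SimulationConfig, "attraction"): AttractionConfig,
    (SimulationConfig, "cycle"): CycleConfig,
    (SimulationConfig, "ode"): OdeConfig,
    (SimulationConfig, "field_init"): FieldInitConfig,
    (SimulationConfig, "tumor_seed"): TumorSeedConfig,
}


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Load a YAML config; missing keys keep their defaults, unknown keys and
    invalid values raise :class:`ConfigError`.  `None` yields the defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    errors: list[str] = []
    cfg = _build(SimulationConfig, data, "", errors)
    if errors:
        raise ConfigError("; ".join(errors))
    return validate_config(cfg)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _check(cond: bool, msg: str, errors: list[str]) -> None:
    if not cond:
        errors.append(msg)


def validate_config(cfg: SimulationConfig) -> SimulationConfig:
    """Range-check every parameter; raises :class:`ConfigError` naming each
    offending dotted path, or returns the config unchanged."""
    e: list[str] = []
    _check(cfg.steps >= 1, f"steps: must be >= 1, got {cfg.steps}", e)
    _check(cfg.replicates >= 1, f"replicates: must be >= 1, got {cfg.replicates}", e)
    _check(cfg.conversion_factor >= 0, "conversion_factor: must be >= 0", e)
    _check(len(cfg.initial_pathway) == 11, "initial_pathway: need 11 species values", e)
    _check(all(v >= 0 for v in cfg.initial_pathway), "initial_pathway: concentrations must be >= 0", e)
    _check(cfg.lattice.nesting >= 1, "lattice.nesting: must be >= 1", e)
    _check(min(cfg.lattice.shape) >= 3, f"lattice.shape: too small {cfg.lattice.shape}", e)
    _check(cfg.lattice.dx_um > 0, "lattice.dx_um: must be > 0", e)
    _check(cfg.diffusion.diffusivity_cm2_s > 0, "diffusion.diffusivity_cm2_s: must be > 0", e)
    _check(cfg.diffusion.n_substeps >= 1, "diffusion.n_substeps: must be >= 1", e)
    _check(cfg.diffusion.dt_substep_s > 0, "diffusion.dt_substep_s: must be > 0", e)
    _check(cfg.diffusion.boundary in ("zero-flux", "dirichlet-zero"),
           f"diffusion.boundary: unknown '{cfg.diffusion.boundary}'", e)
    _check(cfg.diffusion.secretion_nM_s >= 0, "diffusion.secretion_nM_s: must be >= 0", e)
    _check(cfg.diffusion.uptake_rate_per_s >= 0, "diffusion.uptake_rate_per_s: must be >= 0", e)
    _check(cfg.diffusion.uptake_mode in ("linear", "constant"),
           f"diffusion.uptake_mode: unknown '{cfg.diffusion.uptake_mode}'", e)
    _check(0.0 < cfg.attraction.psi < 1.0,
           f"attraction.psi: must be in (0, 1), got {cfg.attraction.psi}", e)
    _check(cfg.attraction.sigma is None or cfg.attraction.sigma >= 0,
           "attraction.sigma: must be >= 0", e)
    _check(cfg.attraction.sigma_rel >= 0, "attraction.sigma_rel: must be >= 0", e)
    _check(cfg.cycle.decision_interval >= 1, "cycle.decision_interval: must be >= 1", e)
    _check(cfg.ode.dt_s > 0, "ode.dt_s: must be > 0", e)
    _check(cfg.ode.seconds_per_step > 0, "ode.seconds_per_step: must be > 0", e)
    _check(cfg.ode.rate_mode in ("relative", "absolute"),
           f"ode.rate_mode: unknown '{cfg.ode.rate_mode}'", e)
    _check(cfg.field_init.kind in ("gaussian", "uniform"),
           f"field_init.kind: unknown '{cfg.field_init.kind}'", e)
    _check(cfg.field_init.amplitude_nM >= 0, "field_init.amplitude_nM: must be >= 0", e)
    _check(cfg.field_init.sigma_frac > 0, "field_init.sigma_frac: must be > 0", e)
    _check(cfg.tumor_seed.kind == "disc", f"tumor_seed.kind: unknown '{cfg.tumor_seed.kind}'", e)
    _check(cfg.tumor_seed.radius >= 0, "tumor_seed.radius: must be >= 0", e)
    _check(cfg.tumor_seed.radius * 2 + 1 <= min(cfg.lattice.shape),
           "tumor_seed.radius: tumor exceeds lattice", e)
    if cfg.diffusion.schwarz is not None:
        s = cfg.diffusion.schwarz
        _check(isinstance(s, dict) and {"tile_shape", "overlap", "iterations"} >= set(s),
               "diffusion.schwarz: expected keys tile_shape/overlap/iterations", e)
        if isinstance(s, dict):
            _check(int(s.get("overlap", 1)) >= 1, "diffusion.schwarz.overlap: must be >= 1", e)
    if e:
        raise ConfigError("; ".join(e))
    return cfg
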