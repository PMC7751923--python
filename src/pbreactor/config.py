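"""Structured-text configuration with unit-suffixed keys.

Configurations are YAML mappings (plain JSON is also valid YAML) whose keys
carry their units explicitly, e.g. ``length_cm``, ``flow_mL_min``,
``cr0_mM``.  Every section is optional: an empty file resolves to the bench
base case (5 cm x 0.4 cm column, 0.628 mL, eps = 0.3, dp = 0.5 mm, 270 mg
enzyme, n-hexane at 30 C, rate constants 4.16/51.17/103.73, feed 150/150/300
mM at 5 mL/min).  Unknown sections or keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import units
from .errors import ConfigError, InvalidInputError
from .geometry import DispersionCorrelation, FluidProperties, ReactorSpec
from .kinetics import PingPongParams
from .model import OperatingPoint, Scenario
from .synth import DEFAULT_SEED

__all__ = ["RunConfig", "load_config", "parse_config", "default_config",
           "default_config_yaml"]


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of reactor, fluid, kinetics, feed and solver settings."""

    reactor: ReactorSpec = field(default_factory=ReactorSpec)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    kinetics: PingPongParams = field(default_factory=PingPongParams)
    operating: OperatingPoint = field(
        default_factory=lambda: OperatingPoint.equimolar(5.0, 300.0))
    correlation: DispersionCorrelation = field(default_factory=DispersionCorrelation)
    n_nodes: int = 201
    rtol: float = 1e-8
    inlet_bc: str = "dirichlet"
    seed: int = DEFAULT_SEED

    def scenario(self) -> Scenario:
        return Scenario(spec=self.reactor, fluid=self.fluid,
                        correlation=self.correlation, kinetics=self.kinetics,
                        n_nodes=self.n_nodes, rtol=self.rtol,
                        inlet_bc=self.inlet_bc)


# section -> {config key: (dataclass field, converter to canonical units)}
_REACTOR_KEYS = {
    "length_cm": ("length_m", lambda v: v * units.CM_TO_M),
    "diameter_cm": ("diameter_m", lambda v: v * units.CM_TO_M),
    "volume_mL": ("volume_m3", lambda v: v * units.ML_TO_M3),
    "void_fraction": ("void_fraction", float),
    "particle_diameter_mm": ("particle_diameter_m", lambda v: v * units.MM_TO_M),
    "enzyme_mass_mg": ("enzyme_mass_kg", lambda v: v * units.MG_TO_KG),
}
_FLUID_KEYS = {
    "density_kg_m3": ("density_kg_m3", float),
    "viscosity_Pa_s": ("viscosity_pa_s", float),
    "label": ("label", str),
}
_KINETICS_KEYS = {
    "vmax_mmol_g_min": ("vmax_mmol_g_min", float),
    "ka_mM": ("ka_mM", float),
    "kr_mM": ("kr_mM", float),
}
_OPERATING_KEYS = {
    "flow_mL_min": ("flow_m3_s", units.ml_min_to_m3_s),
    "cr0_mM": ("cr0_mM", float),
    "cs0_mM": ("cs0_mM", float),
    "ca0_mM": ("ca0_mM", float),
    "temperature_C": ("temperature_c", float),
}
_SOLVER_KEYS = {"n_nodes": int, "rtol": float, "inlet_bc": str}


def _parse_section(name: str, data: dict, keymap: dict, cls):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key not in keymap:
            raise ConfigError(
                f"unknown key '{key}' in section '{name}'; "
                f"expected one of {sorted(keymap)}")
        target, conv = keymap[key]
        try:
            kwargs[target] = conv(value)
        except (TypeError, ValueError) as err:
            raise ConfigError(
                f"key '{name}.{key}': cannot interpret {value!r}: {err}") from err
    try:
        return cls(**kwargs)
    except InvalidInputError as err:
        raise ConfigError(f"invalid section '{name}': {err}") from err


def parse_config(data: dict | None) -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed mapping."""
    data = dict(data or {})
    known = {"reactor", "fluid", "kinetics", "operating", "solver",
             "dispersion_correlation", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown configuration section(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}")

    reactor = _parse_section("reactor", data.get("reactor", {}),
                             _REACTOR_KEYS, ReactorSpec)
    fluid = _parse_section("fluid", data.get("fluid", {}),
                           _FLUID_KEYS, FluidProperties)
    kinetics = _parse_section("kinetics", data.get("kinetics", {}),
                              _KINETICS_KEYS, PingPongParams)
    operating = _parse_section(
        "operating",
        {**{"flow_mL_min": 5.0, "cr0_mM": 150.0, "cs0_mM": 150.0,
            "ca0_mM": 300.0}, **data.get("operating", {})},
        _OPERATING_KEYS, OperatingPoint)

    corr_data = data.get("dispersion_correlation", {})
    if corr_data:
        if not isinstance(corr_data, dict) or \
                set(corr_data) != {"reynolds", "group"}:
            raise ConfigError("section 'dispersion_correlation' must contain "
                              "exactly the keys 'reynolds' and 'group'")
        try:
            correlation = DispersionCorrelation(
                reynolds=tuple(float(v) for v in corr_data["reynolds"]),
                group=tuple(float(v) for v in corr_data["group"]))
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid dispersion correlation: {err}") from err
    else:
        correlation = DispersionCorrelation()

    solver = data.get("solver", {})
    if not isinstance(solver, dict):
        raise ConfigError("section 'solver' must be a mapping")
    unknown = set(solver) - set(_SOLVER_KEYS)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section "
                          f"'solver'; expected a subset of {sorted(_SOLVER_KEYS)}")

    seed = data.get("seed", DEFAULT_SEED)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError(f"'seed' must be a non-negative integer, got {seed!r}")

    try:
        return RunConfig(reactor=reactor, fluid=fluid, kinetics=kinetics,
                         operating=operating, correlation=correlation,
                         n_nodes=int(solver.get("n_nodes", 201)),
                         rtol=float(solver.get("rtol", 1e-8)),
                         inlet_bc=str(solver.get("inlet_bc", "dirichlet")),
                         seed=seed)
    except InvalidInputError as err:
        raise ConfigError(f"invalid solver settings: {err}") from err


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON configuration; ``None`` -> defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root in {path} must be a mapping")
    return parse_config(data)


def default_config() -> RunConfig:
    return RunConfig()


def default_config_yaml() -> str:
    """The bench base case, serialisable back through :func:`load_config`."""
    cfg = RunConfig()
    data = {
        "reactor": {
            "length_cm": cfg.reactor.length_m / units.CM_TO_M,
            "diameter_cm": cfg.reactor.diameter_m / units.CM_TO_M,
            "volume_mL": cfg.reactor.volume_m3 / units.ML_TO_M3,
            "void_fraction": cfg.reactor.void_fraction,
            "particle_diameter_mm": cfg.reactor.particle_diameter_m / units.MM_TO_M,
            "enzyme_mass_mg": cfg.reactor.enzyme_mass_kg / units.MG_TO_KG,
        },
        "fluid": {
            "density_kg_m3": cfg.fluid.density_kg_m3,
            "viscosity_Pa_s": cfg.fluid.viscosity_pa_s,
            "label": cfg.fluid.label,
        },
        "kinetics": {
            "vmax_mmol_g_min": cfg.kinetics.vmax_mmol_g_min,
            "ka_mM": cfg.kinetics.ka_mM,
            "kr_mM": cfg.kinetics.kr_mM,
        },
        "operating": {
            "flow_mL_min": cfg.operating.flow_mL_min,
            "cr0_mM": cfg.operating.cr0_mM,
            "cs0_mM": cfg.operating.cs0_mM,
            "ca0_mM": cfg.operating.ca0_mM,
            "temperature_C": cfg.operating.temperature_c,
        },
        "dispersion_correlation": {
            "reynolds": list(cfg.correlation.reynolds),
            "group": list(cfg.correlation.group),
        },
        "solver": {"n_nodes": cfg.n_nodes, "rtol": cfg.rtol,
                   "inlet_bc": cfg.inlet_bc},
        "seed": cfg.seed,
    }
    return yaml.safe_dump(data, sort_keys=False)
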