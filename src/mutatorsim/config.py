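"""Run configuration: every simulation parameter by name, schema-validated.

Defaults reproduce the published operating point: base growth rate
707.445 (dropped threefold to 235.815 in stationary phase), death rate
0.005, fluctuation rate 0.01, production-penalty coefficient 100, optimal
total concentration 0.4 (dropped tenfold to 0.04 under starvation),
base mutation rate 0.0001, temperatures 0.85 and 1.00.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .cell import FitnessParams
from .evolution import StressProtocol

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass(frozen=True)
class RunConfig:
    # physiology (published defaults)
    b0: float = 707.445
    b0_stationary: float = 235.815
    d: float = 0.005
    r: float = 0.01
    sigma: float = 100.0
    C0: float = 0.4
    C0_starvation: float = 0.04
    m_min: float = 0.0001
    m_max: float = 0.1
    T: float = 0.85
    T_high: float = 1.00
    theta_nat: float = 0.6
    mutator_threshold: float = 0.01
    fluct_sd: float = 0.1

    # population / schedule
    cap: int = 5000
    seed_pop: int = 500
    t_max: int = 25_000
    t_apply: int = 20_000
    protocol: str = "none"  # none | heat_shock | stationary_phase | starvation
    record_every: int = 25

    # structural machinery
    n_structures: int = 10_000
    structure_source: str = "full"  # full (uniform sample) | limit (first-n)
    k_convention: str = "min"

    # seeding and calibration
    master_seed: int = 0
    seed_genes: tuple[str, str, str, str] | None = None
    initial_C: tuple[float, float, float, float] | None = None
    design_p_nat: float = 0.7
    design_p_int: float = 0.4
    calibrate_b0: bool = True
    calibrate_G_ref: bool = True
    G_ref: float = 1.0
    constant_b: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ConfigError("r must be in [0, 1]")
        for name in ("b0", "d", "sigma", "C0", "T", "T_high", "m_min", "m_max",
                     "theta_nat", "fluct_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.protocol not in ("none", "heat_shock", "stationary_phase", "starvation"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")
        if self.structure_source not in ("full", "limit"):
            raise ConfigError("structure_source must be 'full' or 'limit'")
        if self.cap < 1 or self.seed_pop < 1 or self.t_max < 0:
            raise ConfigError("cap, seed_pop must be >= 1 and t_max >= 0")
        if not self.m_min < self.mutator_threshold < self.m_max:
            raise ConfigError("need m_min < mutator_threshold < m_max")
        if self.initial_C is not None:
            if len(self.initial_C) != 4 or any(c <= 0 for c in self.initial_C):
                raise ConfigError("initial_C must be 4 positive values")

    # -- derived objects ---------------------------------------------------

    def fitness_params(self) -> FitnessParams:
        return FitnessParams(
            b0=self.b0, C0=self.C0, sigma=self.sigma, d=self.d,
            theta_nat=self.theta_nat, m_min=self.m_min, m_max=self.m_max,
            G_ref=self.G_ref, r=self.r, T=self.T, fluct_sd=self.fluct_sd,
            mutator_threshold=self.mutator_threshold,
            constant_b=self.constant_b,
        )

    def protocol_obj(self) -> StressProtocol | None:
        if self.protocol == "none":
            return None
        return StressProtocol(
            self.protocol, self.t_apply, heat_T=self.T_high,
            b0_factor=self.b0_stationary / self.b0,
            C0_factor=self.C0_starvation / self.C0,
        )

    def initial_concentrations(self) -> tuple[float, float, float, float]:
        """Equal allocation C0/4 per gene unless explicitly overridden."""
        if self.initial_C is not None:
            return tuple(float(c) for c in self.initial_C)
        return (self.C0 / 4,) * 4


def _coerce(value, target):
    if target is bool or isinstance(target, bool):
        return bool(value)
    return value


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("seed_genes", "initial_C"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    for key in ("seed_genes", "initial_C"):
        if data[key] is not None:
            data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
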