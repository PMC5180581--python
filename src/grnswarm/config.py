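"""Run configuration: every ecological, energetic and genomic parameter.

A simulation run is a pure function of ``(SimConfig, seed)``.  The config is a
tree of frozen-ish dataclasses mirroring the parameter groups of the model
(genome anatomy, mutation rates, GRN dynamics, world/food ecology, seasons,
energy economy, population, ANN baseline, engine).  It serializes to and from
plain YAML so that a run directory always carries an exact echo of the
parameters that produced it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "GenomeConfig",
    "MutationConfig",
    "GrnConfig",
    "WorldConfig",
    "FoodTypeConfig",
    "FoodConfig",
    "SeasonConfig",
    "EnergyConfig",
    "PopulationConfig",
    "AnnConfig",
    "ActionConfig",
    "SensorConfig",
    "SimConfig",
    "default_config",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised when a configuration fails validation before any stepping."""


@dataclass
class GenomeConfig:
    """Artificial-genome anatomy (chromosome count/length, gene layout)."""

    n_chromosomes: int = 10
    chrom_length: int = 10_000
    alphabet: str = "0123"
    promoter: str = "0101"
    type_len: int = 2
    binding_len: int = 5
    payload_len: int = 9
    match_tolerance: int = 2

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("genome dimensions must be positive")
        if len(set(self.alphabet)) < 2 or len(set(self.alphabet)) != len(self.alphabet):
            raise ConfigError("alphabet needs >= 2 distinct characters")
        if any(ch not in self.alphabet for ch in self.promoter):
            raise ConfigError("promoter must be drawn from the alphabet")
        if self.binding_len < 1 or self.payload_len < self.binding_len + 4:
            # payload = signature (binding_len) + 2 wiring chars + 2 value chars
            raise ConfigError("payload must hold signature plus 4 wiring characters")
        if not (0 <= self.match_tolerance <= self.binding_len):
            raise ConfigError("match_tolerance outside [0, binding_len]")


@dataclass
class MutationConfig:
    """Per-replication mutation pressure on the character genome."""

    point_rate: float = 5e-5          # per character
    duplication_rate: float = 0.02    # per chromosome
    duplication_mean_length: int = 50

    def validate(self) -> None:
        if not (0.0 <= self.point_rate <= 1.0 and 0.0 <= self.duplication_rate <= 1.0):
            raise ConfigError("mutation rates must lie in [0, 1]")
        if self.duplication_mean_length < 1:
            raise ConfigError("duplication_mean_length must be >= 1")


@dataclass
class GrnConfig:
    """Agent (gene-product) concentration dynamics."""

    decay: float = 0.2           # fractional decay per step, d
    feedback_gain: float = 0.1   # beta, fitness-feedback modulation
    feedback_scale: float = 1.0  # F, energy units that saturate the feedback term
    c_min: float = 0.1           # deletion threshold
    c_max: float = 5.0           # dosage cap on (re-)expression
    c_init: float = 0.8          # floor concentration of a freshly expressed signalling agent
    repressor_code: int = 0      # payload wiring value (mod 4) that marks a repressor
    cascade_rounds: int = 3      # transduction rounds per step: gene expression
                                 # settles faster than the behavioural timescale

    def validate(self) -> None:
        if not (0.0 < self.decay < 1.0):
            raise ConfigError("decay must lie in (0, 1)")
        if self.c_min < 0 or self.c_max <= 0 or self.c_init < 0:
            raise ConfigError("concentration bounds must be non-negative")
        if self.cascade_rounds < 1:
            raise ConfigError("cascade_rounds must be >= 1")


@dataclass
class WorldConfig:
    size: int = 90
    torus: bool = True
    sensing_radius: int = 1

    def validate(self) -> None:
        if self.size < 3:
            raise ConfigError("world size must be >= 3")
        if self.sensing_radius < 1:
            raise ConfigError("sensing_radius must be >= 1")


@dataclass
class FoodTypeConfig:
    """One food class: minimum energy to access it, energy it delivers, seed count."""

    threshold: float
    energy: float
    initial: int


@dataclass
class FoodConfig:
    types: list[FoodTypeConfig] = field(
        default_factory=lambda: [
            FoodTypeConfig(threshold=0.0, energy=100.0, initial=1200),
            FoodTypeConfig(threshold=30.0, energy=200.0, initial=500),
            FoodTypeConfig(threshold=60.0, energy=400.0, initial=300),
        ]
    )
    r0: float = 0.003  # per-source replication probability at zero crowding
    K: int = 5         # neighbourhood food count at which replication shuts off
    reseed_rate: float = 1.6  # Poisson influx of new sources per step (seed bank)
    restore_schedule: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.types:
            raise ConfigError("at least one food type required")
        thresholds = [t.threshold for t in self.types]
        if thresholds != sorted(thresholds):
            raise ConfigError("food access thresholds must be non-decreasing")
        if any(t.energy <= 0 for t in self.types):
            raise ConfigError("food energy content must be positive")
        if any(t.initial < 0 for t in self.types):
            raise ConfigError("initial food counts must be non-negative")
        if not (0.0 <= self.r0 <= 1.0) or self.K < 1 or self.reseed_rate < 0:
            raise ConfigError("invalid food growth parameters")


@dataclass
class SeasonConfig:
    """Cyclic extra energy costs; one entry per season, 100-step blocks by default."""

    length: int = 100
    # seven-year climate cycle: two mild establishment years, four moderate
    # years, then an escalating year ending in a catastrophic winter
    survival_costs: list[float] = field(
        default_factory=lambda: [0.0, 0.5, 0.5, 1.0, 0.0, 0.5, 0.5, 1.0]
        + [0.5, 1.0, 0.5, 1.0] * 4
        + [1.0, 1.0, 1.5, 4.0])
    movement_costs: list[float] = field(
        default_factory=lambda: [0.0, 1.0, 1.0, 2.0, 0.0, 1.0, 1.0, 2.0]
        + [1.0, 2.0, 1.0, 2.0] * 4
        + [2.0, 2.0, 3.0, 8.0])

    def validate(self) -> None:
        if self.length < 1:
            raise ConfigError("season length must be >= 1")
        if len(self.survival_costs) != len(self.movement_costs) or not self.survival_costs:
            raise ConfigError("season cost tables must be non-empty and equal length")
        if any(c < 0 for c in self.survival_costs + self.movement_costs):
            raise ConfigError("season costs must be non-negative")


@dataclass
class EnergyConfig:
    basic_cost: float = 0.25
    move_cost: float = 0.5
    attack_cost: float = 10.0
    defend_cost: float = 3.0
    defence_bonus: float = 25.0      # strength added when the defend gate fired
    replicate_cost: float = 50.0
    replicate_threshold: float = 600.0
    endowment: float = 150.0          # energy transferred to the offspring
    aggregate_upkeep: float = 0.25   # per member per step
    prey_transfer: float = 0.5       # phi: fraction of victim energy gained

    def validate(self) -> None:
        vals = dataclasses.asdict(self)
        if any(v < 0 for v in vals.values()):
            raise ConfigError("energy costs must be non-negative")
        if not (0.0 <= self.prey_transfer <= 1.0):
            raise ConfigError("prey_transfer must lie in [0, 1]")
        if self.replicate_threshold < self.replicate_cost + self.endowment:
            raise ConfigError("replication threshold must cover cost + endowment")


@dataclass
class PopulationConfig:
    initial: int = 600
    initial_energy: float = 650.0
    initial_energy_spread: float = 0.0  # founders start uniform on
                                        # [E0 - spread, E0 + spread]

    def validate(self) -> None:
        if self.initial < 1 or self.initial_energy <= 0:
            raise ConfigError("population must start positive with positive energy")
        if not (0.0 <= self.initial_energy_spread < self.initial_energy):
            raise ConfigError("initial_energy_spread must lie in [0, initial_energy)")


@dataclass
class AnnConfig:
    hidden: int = 12
    eta: float = 0.01
    trace_decay: float = 0.9
    zero_threshold: float = 1e-3
    zero_window: int = 60
    mutation_sigma: float = 0.05

    def validate(self) -> None:
        if self.hidden < 1 or self.zero_window < 1:
            raise ConfigError("invalid ANN topology/learning parameters")
        if not (0.0 <= self.trace_decay < 1.0):
            raise ConfigError("trace_decay must lie in [0, 1)")


@dataclass
class ActionConfig:
    """Mapping from continuous actuator outputs to discrete actions.

    The move gate has its own (negative) threshold: robots with any live
    movement drive above it keep moving — basal motility — and evolution can
    stop a robot (to save energy) by driving the move output low.
    """

    gate_threshold: float = 0.25
    move_threshold: float = -0.5
    replicate_threshold: float = -0.5  # reproduction is near-automatic once
                                       # the energy precondition holds, unless
                                       # the controller suppresses it

    def validate(self) -> None:
        if not (0.0 < self.gate_threshold < 1.0):
            raise ConfigError("gate_threshold must lie in (0, 1)")
        for name in ("move_threshold", "replicate_threshold"):
            if not (-1.0 < getattr(self, name) < 1.0):
                raise ConfigError(f"{name} must lie in (-1, 1)")


@dataclass
class SensorConfig:
    """Bounded encoding of raw readings onto [0, 1] channels."""

    count_cap: int = 8        # neighbour robot / nearby food counts saturate here
    food_here_cap: int = 2    # own-cell food saturates quickly: one source is salient
    counter_cap: float = 5.0  # recent action counters saturate here
    counter_decay: float = 0.9
    energy_scale: float = 200.0
    rhythm_period: int = 24  # steps per internal activity cycle

    def validate(self) -> None:
        if self.count_cap < 1 or self.counter_cap <= 0 or self.energy_scale <= 0:
            raise ConfigError("sensor scales must be positive")
        if not (0.0 <= self.counter_decay < 1.0):
            raise ConfigError("counter_decay must lie in [0, 1)")


@dataclass
class SimConfig:
    controller: str = "grn"          # "grn" | "ann"
    max_steps: int = 3000
    metrics_interval: int = 10
    extinction_threshold: int = 100
    scarcity_food_threshold: int = 150  # "food-scarce tail" cut for the adaptation analysis
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    grn: GrnConfig = field(default_factory=GrnConfig)
    world: WorldConfig = field(default_factory=WorldConfig)
    food: FoodConfig = field(default_factory=FoodConfig)
    seasons: SeasonConfig = field(default_factory=SeasonConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    ann: AnnConfig = field(default_factory=AnnConfig)
    actions: ActionConfig = field(default_factory=ActionConfig)
    sensors: SensorConfig = field(default_factory=SensorConfig)

    def validate(self) -> "SimConfig":
        if self.controller not in ("grn", "ann"):
            raise ConfigError(f"unknown controller {self.controller!r}")
        if self.max_steps < 0 or self.metrics_interval < 1:
            raise ConfigError("invalid engine bounds")
        if self.extinction_threshold < 0:
            raise ConfigError("extinction_threshold must be >= 0")
        for group in (
            self.genome, self.mutation, self.grn, self.world, self.food,
            self.seasons, self.energy, self.population, self.ann,
            self.actions, self.sensors,
        ):
            group.validate()
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        return _build(cls, data)

    def replace(self, **kwargs: Any) -> "SimConfig":
        """Shallow field replacement returning a new, validated config."""
        return dataclasses.replace(self, **kwargs).validate()


def _build(cls: type, data: Any) -> Any:
    """Recursively construct a dataclass tree from plain dicts/lists."""
    if not dataclasses.is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ConfigError(f"expected mapping for {cls.__name__}, got {type(data).__name__}")
    kwargs: dict[str, Any] = {}
    names = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown config key {cls.__name__}.{key}")
        f = names[key]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.type, str) and f.type in _NESTED):
            sub = _NESTED.get(f.type, f.type) if isinstance(f.type, str) else f.type
            kwargs[key] = _build(sub, value)
        elif key == "types":
            kwargs[key] = [_build(FoodTypeConfig, v) for v in value]
        elif key == "restore_schedule":
            kwargs[key] = {int(k): int(v) for k, v in (value or {}).items()}
        else:
            kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "GenomeConfig": GenomeConfig, "MutationConfig": MutationConfig,
    "GrnConfig": GrnConfig, "WorldConfig": WorldConfig, "FoodConfig": FoodConfig,
    "SeasonConfig": SeasonConfig, "EnergyConfig": EnergyConfig,
    "PopulationConfig": PopulationConfig, "AnnConfig": AnnConfig,
    "ActionConfig": ActionConfig, "SensorConfig": SensorConfig,
    "FoodTypeConfig": FoodTypeConfig,
}


def default_config(**overrides: Any) -> SimConfig:
    """The package's declared default study conditions."""
    return SimConfig(**overrides).validate()


def load_config(path: str) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data).validate()


def save_config(cfg: SimConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
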