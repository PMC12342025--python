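"""Run configuration objects and YAML handling.

All stochastic components draw their seeds from a single master seed via
``numpy.random.SeedSequence``, so any artifact of a run is reproducible from
the configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

from .errors import ConfigurationError

#: Default per-cell-type census for the 30x30 grid.
DEFAULT_CENSUS = {
    "macrophage": 30,
    "neutrophil": 30,
    "TH0": 20,
    "TH1": 5,
    "TH2": 5,
    "precursor": 20,
}


@dataclass
class SimulationConfig:
    """Parameters of one agent-based simulation run.

    The grid is toroidal; endothelium tiles every site and mobile immune cells
    move over it. ``injury_size`` is the number of contiguous endothelial
    sites initially damaged. Time is in abstract steps; ``steps_per_day``
    maps steps to clinical days when aligning with reference data.
    """

    grid_width: int = 30
    grid_height: int = 30
    census: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CENSUS))
    injury_size: int = 120
    duration: int = 199  # ten days at 20 steps/day, with every day-bin full width
    sampling_interval: int = 1
    seed: int = 0
    replicate_count: int = 20
    steps_per_day: float = 20.0
    death_threshold: float = 0.2
    resolve_threshold: float = 0.8
    diffusion: float = 0.15
    decay: float = 0.05
    decay_overrides: dict[str, float] = field(
        default_factory=lambda: {"DAMP": 0.03, "cytotox": 0.35}
    )
    chemotaxis_threshold: float = 0.05
    injury_damp_release: float = 2.0

    def __post_init__(self):
        if self.grid_width < 1 or self.grid_height < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if any(v < 0 for v in self.census.values()):
            raise ConfigurationError("census counts must be nonnegative")
        if self.injury_size < 0 or self.injury_size > self.grid_area:
            raise ConfigurationError("injury_size must be within [0, grid area]")
        if not (self.duration >= self.sampling_interval >= 1):
            raise ConfigurationError("require duration >= sampling_interval >= 1")
        if not 0 < self.diffusion <= 0.25 or not 0 <= self.decay < 1:
            raise ConfigurationError("diffusion in (0, 0.25], decay in [0, 1) required")

    @property
    def grid_area(self) -> int:
        return self.grid_width * self.grid_height


def toy_simulation_config(**overrides: Any) -> SimulationConfig:
    """A small, fast configuration used for calibration-scale experiments."""
    defaults = dict(
        grid_width=12,
        grid_height=12,
        census={
            "macrophage": 8,
            "neutrophil": 8,
            "TH0": 6,
            "TH1": 2,
            "TH2": 2,
            "precursor": 6,
        },
        injury_size=20,
        duration=89,  # nine full day-bins at 10 steps/day
        sampling_interval=1,
        steps_per_day=10.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class GAConfig:
    """Genetic-algorithm settings for the enrichment search."""

    population_size: int = 24
    generations: int = 30
    elite_count: int = 2
    mutation_rate: float = 0.05
    mutation_scale: float = 0.5
    replicates_per_eval: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if not 0 <= self.elite_count < self.population_size:
            raise ConfigurationError("elite_count must be < population_size")
        if self.generations < 1 or self.replicates_per_eval < 2:
            raise ConfigurationError(
                "generations >= 1 and replicates_per_eval >= 2 required"
            )


@dataclass
class ALConfig:
    """Active-learning settings for mapping the non-falsifiable boundary."""

    batch_size: int = 200
    rounds: int = 5
    pool_size: int = 400
    perturb_rate: float = 0.02
    perturb_scale: float = 1.0
    stop_tolerance: float = 0.0  # epsilon on RangeMatrix change; 0 disables early stop
    surrogate_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1 or self.batch_size < 1:
            raise ConfigurationError("rounds >= 1 and batch_size >= 1 required")
        if self.pool_size < self.batch_size:
            raise ConfigurationError("pool_size must be >= batch_size")


@dataclass
class ReferenceConfig:
    """Settings for synthetic clinical-style reference generation."""

    subjects_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"A": 20, "B": 20}
    )
    # one hidden parameterization per cohort: within-cohort heterogeneity
    # comes from varied injury sizes and intrinsic stochasticity, so every
    # observation bin is attainable by its cohort's own parameterization
    hidden_mrms_per_cohort: int = 1
    samples_per_subject: tuple[int, int] = (3, 8)
    noise_sigma: float = 0.5  # lognormal sigma; multiplexed panels span ~an order of magnitude
    injury_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"A": (10, 22), "B": (24, 40)}
    )
    perturb_elements: int = 6
    perturb_magnitude: float = 0.8
    # optional magnitude floor on hidden offsets; 0 keeps offsets uniform on
    # [-magnitude, +magnitude], so cohort-mates stay mutually compatible
    perturb_floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.subjects_per_cohort.values()):
            raise ConfigurationError("each cohort needs at least one subject")
        lo, hi = self.samples_per_subject
        if not 1 <= lo <= hi:
            raise ConfigurationError("samples_per_subject must be 1 <= lo <= hi")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be nonnegative")


@dataclass
class RunConfig:
    """Composite configuration for the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=toy_simulation_config)
    ga: GAConfig = field(default_factory=GAConfig)
    al: ALConfig = field(default_factory=ALConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    master_seed: int = 0
    bin_width: float = 1.0       # envelope bin width in clinical days
    alpha: float = 1.5           # envelope expansion: observed extremes are samples, not bounds
    per_member_replicates: int = 3
    output_dir: str = "smtgen-output"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "ga": GAConfig,
    "al": ALConfig,
    "reference": ReferenceConfig,
}


def _coerce_section(name: str, cls, payload: dict):
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{name}: expected a mapping")
    valid = {f for f in cls.__dataclass_fields__}
    for key in payload:
        if key not in valid:
            raise ConfigurationError(f"{name}.{key}: unknown field")
    # YAML gives lists where dataclasses expect tuples
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    if "injury_range" in coerced and isinstance(coerced["injury_range"], dict):
        coerced["injury_range"] = {
            c: tuple(r) for c, r in coerced["injury_range"].items()
        }
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigurationError(f"{name}: {exc}") from exc


def load_run_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration; errors name the field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("top level of run config must be a mapping")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _coerce_section(key, _SECTION_TYPES[key], value)
        elif key in ("master_seed", "bin_width", "alpha", "per_member_replicates",
                     "output_dir"):
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown top-level field {key!r}")
    return RunConfig(**kwargs)


def save_run_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def spawn_seed(master_seed: int, *key: int) -> int:
    """Derive a child seed (< 2**31) from a master seed and an index path."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))
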