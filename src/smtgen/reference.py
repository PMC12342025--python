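"""Sparse clinical-style reference observations and falsification envelopes.

Real multiplexed cytokine panels are sampled a handful of times per subject at
irregular intervals, and the within-cohort spread of each mediator typically
exceeds the between-cohort difference in means — which is why downstream
falsification consumes only per-bin min/max envelopes and never assumes a
parametric distribution. This module reads and writes such observation
tables, builds the envelopes, and generates synthetic reference datasets with
the same pathologies (sparsity, irregular sampling, cohort overlap,
multiplicative noise) from hidden ground-truth Model Rule Matrices, so that
calibration can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import run_simulation
from .config import ReferenceConfig, SimulationConfig, spawn_seed
from .errors import ParameterError, ValidationError
from .mrm import ModelRuleMatrix, build_base_mrm

REFERENCE_COLUMNS = ("subject_id", "cohort", "time", "entity", "value")


@dataclass
class ReferenceDataset:
    """Long-format observation table: (subject_id, cohort, time, entity, value).

    ``time`` is in clinical days. Values are nonnegative concentrations in
    arbitrary units; each subject belongs to exactly one cohort.
    """

    observations: pd.DataFrame
    allowed_entities: tuple[str, ...] | None = None

    def __post_init__(self):
        self.observations = self.observations.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.observations
        missing = set(REFERENCE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        bad = df.index[df["value"] < 0].tolist()
        if bad:
            raise ValidationError(f"negative values at rows {bad}", bad)
        if self.allowed_entities is not None:
            unknown = df.index[~df["entity"].isin(self.allowed_entities)].tolist()
            if unknown:
                raise ValidationError(f"unknown entities at rows {unknown}", unknown)
        dup = df.duplicated(subset=["subject_id", "time", "entity"], keep=False)
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValidationError(f"duplicate (subject, time, entity) rows {rows}", rows)
        multi = df.groupby("subject_id")["cohort"].nunique()
        conflicted = multi.index[multi > 1].tolist()
        if conflicted:
            raise ValidationError(f"subjects in more than one cohort: {conflicted}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def cohorts(self) -> tuple[str, ...]:
        return tuple(sorted(self.observations["cohort"].unique()))

    @property
    def entities(self) -> tuple[str, ...]:
        return tuple(sorted(self.observations["entity"].unique()))

    def cohort_stats(self) -> pd.DataFrame:
        """Per (cohort, entity): mean, min, max over all observations."""
        return (
            self.observations.groupby(["cohort", "entity"])["value"]
            .agg(["mean", "min", "max"])
            .reset_index()
        )

    def overlap_property_holds(self) -> bool:
        """True iff, per entity, |mean_A - mean_B| < within-cohort range for
        every cohort pair — the regime where means cannot discriminate."""
        stats = self.cohort_stats().set_index(["cohort", "entity"])
        cohorts = self.cohorts
        for entity in self.entities:
            for a in cohorts:
                for b in cohorts:
                    if a >= b:
                        continue
                    try:
                        sa = stats.loc[(a, entity)]
                        sb = stats.loc[(b, entity)]
                    except KeyError:
                        continue
                    gap = abs(sa["mean"] - sb["mean"])
                    if gap >= (sa["max"] - sa["min"]):
                        return False
        return True


def load_reference(path: str, allowed_entities: tuple[str, ...] | None = None) -> ReferenceDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    return ReferenceDataset(df, allowed_entities=allowed_entities)


def save_reference(dataset: ReferenceDataset, path: str) -> None:
    dataset.observations.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class Envelope:
    """Per (cohort, entity, time-bin) observation bands used for falsification.

    ``bounds[cohort][entity][bin_start] = (lower, upper)``; ``bin_start`` is in
    clinical days, bins cover [bin_start, bin_start + bin_width). ``alpha`` >= 1
    widens each band symmetrically about its midpoint — observed extremes are
    treated as samples from a wider attainable range, never as true bounds.
    """

    bounds: dict
    bin_width: float
    alpha: float

    def constrained_bins(self, cohort: str) -> list[tuple[str, float, float, float]]:
        """(entity, bin_start, lower, upper) for every constrained bin."""
        out = []
        for entity, bins in self.bounds.get(cohort, {}).items():
            for bin_start, (lo, hi) in sorted(bins.items()):
                out.append((entity, bin_start, lo, hi))
        return out

    @property
    def cohorts(self) -> tuple[str, ...]:
        return tuple(sorted(self.bounds))

    def to_jsonable(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "alpha": self.alpha,
            "bounds": {
                c: {e: {str(b): list(v) for b, v in bins.items()}
                    for e, bins in ents.items()}
                for c, ents in self.bounds.items()
            },
        }

    @classmethod
    def from_jsonable(cls, payload: dict) -> "Envelope":
        bounds = {
            c: {e: {float(b): tuple(v) for b, v in bins.items()}
                for e, bins in ents.items()}
            for c, ents in payload["bounds"].items()
        }
        return cls(bounds=bounds, bin_width=payload["bin_width"], alpha=payload["alpha"])


def build_envelope(
    data: ReferenceDataset,
    bin_width: float = 1.0,
    alpha: float = 1.0,
) -> Envelope:
    """Bin observations by flooring time and take per-bin min/max bands.

    With ``alpha`` > 1 each band's half-width is multiplied by alpha about its
    midpoint. Empty bins carry no constraint.
    """
    if len(data) == 0:
        raise ParameterError("cannot build an envelope from an empty dataset")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if alpha < 1.0:
        raise ParameterError("alpha must be >= 1 (widening only)")
    df = data.observations.copy()
    df["bin_start"] = np.floor(df["time"] / bin_width) * bin_width
    bounds: dict = {}
    grouped = df.groupby(["cohort", "entity", "bin_start"])["value"].agg(["min", "max"])
    for (cohort, entity, bin_start), row in grouped.iterrows():
        lo, hi = float(row["min"]), float(row["max"])
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        half *= alpha
        bounds.setdefault(cohort, {}).setdefault(entity, {})[float(bin_start)] = (
            mid - half, mid + half,
        )
    return Envelope(bounds=bounds, bin_width=bin_width, alpha=alpha)


@dataclass
class SyntheticTruth:
    """Hidden ground truth behind a synthetic reference dataset."""

    mrms: list[tuple[str, ModelRuleMatrix]]       # (cohort, hidden MRM)
    perturbed_elements: list[tuple[int, int]]     # declared perturbed (rule, entity)
    subject_assignments: dict[str, tuple[str, int, int]]  # subject -> (cohort, mrm index, injury)

    @property
    def hidden_mrms(self) -> list[ModelRuleMatrix]:
        return [m for _, m in self.mrms]


def generate_synthetic_reference(
    config: ReferenceConfig,
    sim_config: SimulationConfig,
    base: ModelRuleMatrix | None = None,
    seed: int | None = None,
) -> tuple[ReferenceDataset, SyntheticTruth]:
    """Emulate a sparse two-cohort multiplexed-cytokine study.

    Hidden ground-truth MRMs are drawn per cohort by perturbing a declared
    subset of base-MRM elements; each subject is simulated with a
    subject-specific hidden MRM and injury size, then sampled at sparse
    irregular clinical times with multiplicative lognormal noise. The returned
    truth object enables parameter-recovery testing.
    """
    base = base or build_base_mrm()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))

    n_rules, n_entities = base.shape
    flat = rng.choice(n_rules * n_entities, size=config.perturb_elements, replace=False)
    perturbed = [(int(k // n_entities), int(k % n_entities)) for k in flat]

    cohorts = sorted(config.subjects_per_cohort)
    if not cohorts:
        raise ParameterError("at least one cohort required")
    hidden: list[tuple[str, ModelRuleMatrix]] = []
    lo_b, hi_b = base.bounds
    floor = min(config.perturb_floor, config.perturb_magnitude)
    for cohort in cohorts:
        for _ in range(config.hidden_mrms_per_cohort):
            values = base.values.copy()
            for (i, j) in perturbed:
                magnitude = rng.uniform(floor, config.perturb_magnitude)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                values[i, j] = np.clip(values[i, j] + sign * magnitude, lo_b, hi_b)
            hidden.append((cohort, base.copy_with(values)))

    records = []
    assignments: dict[str, tuple[str, int, int]] = {}
    obs_names = base.entities.observed_names
    obs_idx = list(base.entities.observed_subset)
    lo_s, hi_s = config.samples_per_subject
    subject_counter = 0
    for cohort in cohorts:
        cohort_mrms = [k for k, (c, _) in enumerate(hidden) if c == cohort]
        inj_lo, inj_hi = config.injury_range.get(
            cohort, (sim_config.injury_size, sim_config.injury_size)
        )
        for s in range(config.subjects_per_cohort[cohort]):
            subject_id = f"{cohort}{s:03d}"
            mrm_k = cohort_mrms[int(rng.integers(len(cohort_mrms)))]
            injury = int(rng.integers(inj_lo, inj_hi + 1))
            cfg = SimulationConfig(**{**sim_config.__dict__, "injury_size": injury})
            run_seed = spawn_seed(seed, 1, subject_counter)
            traj = run_simulation(cfg, hidden[mrm_k][1], seed=run_seed)
            assignments[subject_id] = (cohort, mrm_k, injury)

            n_samples = int(rng.integers(lo_s, hi_s + 1))
            n_samples = min(n_samples, traj.times.size)
            pick = np.sort(rng.choice(traj.times.size, size=n_samples, replace=False))
            days = traj.times[pick] / cfg.steps_per_day
            for t_idx, day in zip(pick, days):
                noise = (
                    np.exp(config.noise_sigma * rng.standard_normal(len(obs_idx)))
                    if config.noise_sigma > 0
                    else np.ones(len(obs_idx))
                )
                vals = traj.values[t_idx, obs_idx] * noise
                for name, v in zip(obs_names, vals):
                    records.append((subject_id, cohort, float(day), name, float(v)))
            subject_counter += 1

    if not records:
        raise ParameterError("generation produced an empty dataset")
    df = pd.DataFrame(records, columns=list(REFERENCE_COLUMNS))
    dataset = ReferenceDataset(df, allowed_entities=obs_names)
    truth = SyntheticTruth(
        mrms=hidden, perturbed_elements=perturbed, subject_assignments=assignments,
    )
    return dataset, truth
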