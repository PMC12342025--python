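"""Synthetic mediator trajectory (SMT) spaces from a calibrated ensemble.

Running every valid-ensemble member with stochastic replicates yields a
labeled trajectory space per cohort: dense mediator time series at the
simulation cadence, far denser than the sparse clinical-style reference they
were calibrated to. This module computes the cohort envelopes, the separation
profile (times at which the two cohorts' envelopes are disjoint — candidate
discriminative sampling points that sparse real-world sampling can miss), the
expansion summary (how far the synthetic envelope extends beyond observed
extremes), and ML-ready CSV exports.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abm import run_simulation
from .calibration import ValidEnsemble
from .config import SimulationConfig, spawn_seed
from .errors import ParameterError
from .reference import ReferenceDataset


@dataclass
class SMTTrajectory:
    """One dense simulated trajectory with full provenance."""

    run_id: str
    mrm_id: str
    cohort: str
    seed: int
    outcome: str
    times: np.ndarray            # step indices
    values: np.ndarray           # (n_times, n_entities)


@dataclass
class SMTDataset:
    """Labeled synthetic trajectory space: trajectories + cohort envelopes."""

    trajectories: list[SMTTrajectory]
    entities: tuple[str, ...]
    steps_per_day: float
    config_hash: str
    master_seed: int
    envelopes: dict = field(default_factory=dict)
    # cohort -> {"times": steps, "min": (t, e), "max": (t, e)}

    @property
    def cohorts(self) -> tuple[str, ...]:
        return tuple(sorted({t.cohort for t in self.trajectories}))

    def compute_envelopes(self) -> None:
        self.envelopes = {}
        for cohort in self.cohorts:
            members = [t for t in self.trajectories if t.cohort == cohort]
            all_times = np.unique(np.concatenate([t.times for t in members]))
            n_ent = len(self.entities)
            lo = np.full((all_times.size, n_ent), np.inf)
            hi = np.full((all_times.size, n_ent), -np.inf)
            for t in members:
                pos = np.searchsorted(all_times, t.times)
                lo[pos] = np.minimum(lo[pos], t.values)
                hi[pos] = np.maximum(hi[pos], t.values)
            self.envelopes[cohort] = {"times": all_times, "min": lo, "max": hi}


def _config_hash(sim_config: SimulationConfig, master_seed: int,
                 per_member_replicates: int, injury_ranges: dict | None = None) -> str:
    payload = json.dumps(
        {"sim": sim_config.__dict__, "master_seed": master_seed,
         "per_member_replicates": per_member_replicates,
         "injury_ranges": injury_ranges},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_smt(
    ensemble: ValidEnsemble,
    per_member_replicates: int,
    sim_config: SimulationConfig,
    master_seed: int = 0,
    injury_ranges: dict | None = None,
) -> SMTDataset:
    """Simulate every ensemble member with seeded replicates.

    Dataset size = members x replicates. Each trajectory carries its source
    member's cohort tag and its own simulated outcome; replicate seeds derive
    from (master_seed, member index, replicate index) so the dataset is
    byte-reproducible. ``injury_ranges`` (cohort -> (lo, hi)) spreads replicate
    injury sizes over each cohort's insult range, matching how the cohort was
    calibrated.
    """
    if per_member_replicates < 1:
        raise ParameterError("per_member_replicates must be >= 1")
    if len(ensemble) == 0:
        raise ParameterError("cannot generate SMT from an empty ensemble")
    entities = ensemble.members[0].mrm.entities.names
    trajectories = []
    for mi, member in enumerate(ensemble.members):
        inj = (injury_ranges or {}).get(member.cohort)
        for k in range(per_member_replicates):
            seed = spawn_seed(master_seed, mi, k)
            cfg = sim_config
            if inj is not None:
                lo, hi = inj
                size = int(round(lo + (hi - lo) * k / max(per_member_replicates - 1, 1)))
                cfg = SimulationConfig(**{**sim_config.__dict__, "injury_size": size})
            traj = run_simulation(cfg, member.mrm, seed=seed,
                                  mrm_id=member.member_id)
            trajectories.append(SMTTrajectory(
                run_id=f"{member.member_id}-r{k}",
                mrm_id=member.member_id,
                cohort=member.cohort,
                seed=seed,
                outcome=traj.outcome,
                times=traj.times,
                values=traj.values,
            ))
    dataset = SMTDataset(
        trajectories=trajectories,
        entities=entities,
        steps_per_day=sim_config.steps_per_day,
        config_hash=_config_hash(sim_config, master_seed, per_member_replicates,
                                 injury_ranges),
        master_seed=master_seed,
    )
    dataset.compute_envelopes()
    return dataset


@dataclass
class SeparationProfile:
    """Where the two cohorts' trajectory-space envelopes come apart."""

    entities: tuple[str, ...]
    disjoint_intervals: dict     # entity -> list of (start_step, end_step)
    overlap_fraction: dict       # entity -> fraction of common times NOT disjoint

    def n_disjoint_regions(self) -> int:
        return sum(len(v) for v in self.disjoint_intervals.values())


def compute_separation(dataset: SMTDataset) -> SeparationProfile:
    """Per entity, the time intervals where cohort envelopes are disjoint.

    A sampled time is disjoint for an entity iff [minA, maxA] and [minB, maxB]
    do not intersect there; contiguous disjoint times merge into intervals.
    """
    cohorts = dataset.cohorts
    if len(cohorts) < 2:
        raise ParameterError("separation requires both cohorts present")
    a, b = cohorts[0], cohorts[1]
    if not dataset.envelopes:
        dataset.compute_envelopes()
    env_a, env_b = dataset.envelopes[a], dataset.envelopes[b]
    common, ia, ib = np.intersect1d(env_a["times"], env_b["times"],
                                    return_indices=True)
    intervals: dict = {}
    overlap: dict = {}
    for j, entity in enumerate(dataset.entities):
        lo_a, hi_a = env_a["min"][ia, j], env_a["max"][ia, j]
        lo_b, hi_b = env_b["min"][ib, j], env_b["max"][ib, j]
        disjoint = (hi_a < lo_b) | (hi_b < lo_a)
        runs = []
        start = None
        for t, d in zip(common, disjoint):
            if d and start is None:
                start = t
            elif not d and start is not None:
                runs.append((int(start), int(prev)))
                start = None
            prev = t
        if start is not None:
            runs.append((int(start), int(common[-1])))
        intervals[entity] = runs
        overlap[entity] = float(1.0 - disjoint.mean()) if common.size else 1.0
    return SeparationProfile(
        entities=dataset.entities,
        disjoint_intervals=intervals,
        overlap_fraction=overlap,
    )


@dataclass
class ExpansionSummary:
    """How far the SMT envelope extends beyond observed reference extremes."""

    extension_low: dict          # entity -> magnitude below reference min (>= 0)
    extension_high: dict         # entity -> magnitude above reference max (>= 0)

    def expanded_entities(self) -> list[str]:
        return [e for e in self.extension_low
                if self.extension_low[e] > 0 or self.extension_high[e] > 0]


def expansion_check(dataset: SMTDataset, reference: ReferenceDataset) -> ExpansionSummary:
    """Per shared entity, report extension of the SMT envelope beyond the
    observed reference [min, max] — the expansiveness requirement: observed
    extremes are samples, not bounds, and the generator must be able to reach
    past them."""
    ref_stats = reference.observations.groupby("entity")["value"].agg(["min", "max"])
    if not dataset.envelopes:
        dataset.compute_envelopes()
    lo_all = np.min([env["min"] for env in dataset.envelopes.values()], axis=0)
    hi_all = np.max([env["max"] for env in dataset.envelopes.values()], axis=0)
    ext_low, ext_high = {}, {}
    for j, entity in enumerate(dataset.entities):
        if entity not in ref_stats.index:
            continue
        smt_min = float(np.min(lo_all[:, j]))
        smt_max = float(np.max(hi_all[:, j]))
        ext_low[entity] = max(0.0, float(ref_stats.loc[entity, "min"]) - smt_min)
        ext_high[entity] = max(0.0, smt_max - float(ref_stats.loc[entity, "max"]))
    return ExpansionSummary(extension_low=ext_low, extension_high=ext_high)


# -- export ------------------------------------------------------------------

CSV_LONG = "csv-long"
CSV_WIDE = "csv-wide"


def export_smt(dataset: SMTDataset, path: str, format: str = CSV_LONG) -> str:
    """Write the dataset as CSV plus a manifest JSON; returns the CSV path.

    csv-long: one row per (run, time, entity). csv-wide: one row per
    (run, time) with one column per entity plus label columns.
    """
    if format not in (CSV_LONG, CSV_WIDE):
        raise ParameterError(f"unknown export format {format!r}")
    os.makedirs(path, exist_ok=True)
    rows = []
    if format == CSV_LONG:
        for t in dataset.trajectories:
            for ti, time in enumerate(t.times):
                for j, entity in enumerate(dataset.entities):
                    rows.append((t.run_id, t.mrm_id, t.cohort, t.seed,
                                 int(time), entity, t.values[ti, j]))
        df = pd.DataFrame(rows, columns=["run_id", "mrm_id", "cohort", "seed",
                                         "time", "entity", "value"])
        csv_path = os.path.join(path, "smt_long.csv")
    else:
        for t in dataset.trajectories:
            for ti, time in enumerate(t.times):
                rows.append((t.run_id, t.mrm_id, t.cohort, t.seed, t.outcome,
                             int(time), *t.values[ti]))
        df = pd.DataFrame(rows, columns=["run_id", "mrm_id", "cohort", "seed",
                                         "outcome", "time", *dataset.entities])
        csv_path = os.path.join(path, "smt_wide.csv")
    df.to_csv(csv_path, index=False, float_format="%.17g")  # exact float64 round trip
    manifest = {
        "format": format,
        "config_hash": dataset.config_hash,
        "master_seed": dataset.master_seed,
        "entities": list(dataset.entities),
        "steps_per_day": dataset.steps_per_day,
        "n_trajectories": len(dataset.trajectories),
        "outcomes": {t.run_id: t.outcome for t in dataset.trajectories},
        "cohorts": list(dataset.cohorts),
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return csv_path


def load_smt(path: str) -> SMTDataset:
    """Reload a csv-long export (lossless round trip)."""
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest["format"] != CSV_LONG:
        raise ParameterError("only csv-long exports can be reloaded")
    df = pd.read_csv(os.path.join(path, "smt_long.csv"), float_precision="round_trip")
    entities = tuple(manifest["entities"])
    trajectories = []
    for run_id, grp in df.groupby("run_id", sort=False):
        wide = grp.pivot(index="time", columns="entity", values="value")
        wide = wide[list(entities)].sort_index()
        first = grp.iloc[0]
        trajectories.append(SMTTrajectory(
            run_id=run_id,
            mrm_id=first["mrm_id"],
            cohort=first["cohort"],
            seed=int(first["seed"]),
            outcome=manifest["outcomes"][run_id],
            times=wide.index.to_numpy(),
            values=wide.to_numpy(),
        ))
    dataset = SMTDataset(
        trajectories=trajectories,
        entities=entities,
        steps_per_day=manifest["steps_per_day"],
        config_hash=manifest["config_hash"],
        master_seed=manifest["master_seed"],
    )
    dataset.compute_envelopes()
    return dataset
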