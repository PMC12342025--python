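"""Stochastic 2-D agent-based model of the endothelial-blood interface.

The grid is a torus tiled by endothelial cells, each carrying a damage level
in [0, 1]; mobile immune cells (macrophages, neutrophils, TH0/TH1/TH2
lymphocytes, precursors) move over it. Seventeen mediator entities live on
per-entity concentration lattices that diffuse (4-neighbor explicit kernel)
and decay multiplicatively each step.

Every behavioral rule r computes a local drive

    d = sum_j M[r, j] * c_j + bias_r

from the mediator concentrations c at the agent's site, where M is the Model
Rule Matrix, and passes it through a bounded response (logistic for
activation/differentiation/death probabilities, clipped-linear for secretion
and clearance rates). Injury seeds a contiguous damaged patch that releases a
damage signal (DAMP); the canonical base parameterization then drives a
forward loop (DAMP -> macrophage activation -> TNFa/IL-1b -> neutrophil
recruitment -> cytotoxic effectors -> further damage) checked by
anti-inflammatory mediators, DAMP clearance and healing. Whether the loop
resolves or runs away depends on injury size, with a stochastic regime in
between — the model's source of trajectory heterogeneity at fixed
parameterization.

All randomness flows through a single seeded ``numpy.random.Generator``;
identical (config, MRM, seed) triples reproduce trajectories exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import catalogs as cat
from .config import SimulationConfig
from .errors import ConfigurationError, ParameterError
from .mrm import ModelRuleMatrix

# outcome labels
RESOLVED = "resolved"
PERSISTENT = "persistent-inflammation"
DEAD = "dead"

# mobile cell type codes (endothelium is the lattice itself)
_MOBILE_TYPES = (
    cat.MACROPHAGE, cat.NEUTROPHIL, cat.TH0, cat.TH1, cat.TH2, cat.PRECURSOR,
)
_TYPE_CODE = {t: i for i, t in enumerate(_MOBILE_TYPES)}

#: maximum age (steps) per mobile type; neutrophils are short-lived
_LIFESPAN = {
    cat.MACROPHAGE: 10_000,
    cat.NEUTROPHIL: 60,
    cat.TH0: 10_000,
    cat.TH1: 10_000,
    cat.TH2: 10_000,
    cat.PRECURSOR: 10_000,
}


@dataclass
class Trajectory:
    """Dense sampled output of one run: grid-mean mediator concentrations."""

    times: np.ndarray            # sampled step indices
    values: np.ndarray           # (n_samples, n_entities) grid-mean concentration
    health: np.ndarray           # (n_samples,) fraction of endothelium intact
    outcome: str
    seed: int
    mrm_id: str = ""

    @property
    def terminal_health(self) -> float:
        return float(self.health[-1])

    def times_days(self, steps_per_day: float) -> np.ndarray:
        return self.times / steps_per_day


@dataclass
class TrajectorySpace:
    """Replicate trajectories of one (MRM, config) plus their min/max envelope."""

    replicates: list[Trajectory]
    envelope_times: np.ndarray   # union of sampled steps, ascending
    envelope_min: np.ndarray     # (n_times, n_entities)
    envelope_max: np.ndarray


@dataclass
class WorldState:
    """Full mutable state of a running simulation."""

    config: SimulationConfig
    fields: np.ndarray           # (n_entities, H, W)
    damage: np.ndarray           # (H, W) endothelial damage in [0, 1]
    type_code: np.ndarray        # (capacity,) int8
    rows: np.ndarray             # (capacity,) int32
    cols: np.ndarray
    activation: np.ndarray       # (capacity,) float in [0, 1]
    age: np.ndarray              # (capacity,) int32
    alive: np.ndarray            # (capacity,) bool
    t: int = 0

    @property
    def health(self) -> float:
        return float(1.0 - self.damage.mean())

    def mediator_aggregates(self) -> np.ndarray:
        return self.fields.mean(axis=(1, 2))

    def census(self) -> dict[str, int]:
        out = {}
        for t, code in _TYPE_CODE.items():
            out[t] = int(np.sum(self.alive & (self.type_code == code)))
        return out


class _CompiledRules:
    """MRM + catalog flattened into arrays for fast per-step evaluation."""

    def __init__(self, mrm: ModelRuleMatrix, config: SimulationConfig | None = None):
        self.mrm = mrm
        ents = mrm.entities
        self.n_entities = len(ents)
        self.weights = mrm.values        # (25, 17)
        rules = mrm.rules.rules
        self.bias = np.array([r.bias for r in rules])
        self.rate = np.array([r.rate for r in rules])
        self.logistic = np.array([r.response == cat.LOGISTIC for r in rules])
        # index rules by owner type, with per-owner stacked weights for one-shot drives
        self.by_owner: dict[str, list[int]] = {t: [] for t in cat.CELL_TYPES}
        for i, r in enumerate(rules):
            self.by_owner[r.owner].append(i)
        self.owner_weights = {
            t: self.weights[idx].T.copy() for t, idx in self.by_owner.items()
        }  # (entities, k)
        self.owner_bias = {t: self.bias[idx] for t, idx in self.by_owner.items()}
        self.rules = rules
        # resolve secretion/clearance targets to entity columns
        self.target_entity = {}
        for i, r in enumerate(rules):
            if r.family in (cat.UPREGULATION, cat.DOWNREGULATION):
                self.target_entity[i] = ents.index(r.target)
        self.damp_idx = ents.index("DAMP")
        self.il8_idx = ents.index("IL-8")
        self.decay = None
        if config is not None:
            self.decay = np.full(self.n_entities, config.decay)
            for name, value in config.decay_overrides.items():
                try:
                    self.decay[ents.index(name)] = value
                except ValueError:
                    pass

    def response_at(self, rule_idx: int, biased_drive: np.ndarray) -> np.ndarray:
        """Bounded response for a drive that already includes the rule bias."""
        if self.logistic[rule_idx]:
            return 1.0 / (1.0 + np.exp(-biased_drive))
        return np.minimum(np.maximum(biased_drive, 0.0), 1.0)


def _grow_patch(h: int, w: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Random contiguous patch of `size` sites on an h x w torus (bool mask)."""
    mask = np.zeros((h, w), dtype=bool)
    if size == 0:
        return mask
    r0, c0 = int(rng.integers(h)), int(rng.integers(w))
    mask[r0, c0] = True
    frontier = [(r0, c0)]
    count = 1
    while count < size and frontier:
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        neighbors = [((r - 1) % h, c), ((r + 1) % h, c), (r, (c - 1) % w), (r, (c + 1) % w)]
        fresh = [(rr, cc) for rr, cc in neighbors if not mask[rr, cc]]
        if not fresh:
            frontier.pop(idx)
            continue
        rr, cc = fresh[int(rng.integers(len(fresh)))]
        mask[rr, cc] = True
        frontier.append((rr, cc))
        count += 1
    return mask


def initialize(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_entities: int = 17,
) -> WorldState:
    """Place agents, apply injury, and release the initial damage signal."""
    h, w = config.grid_height, config.grid_width
    total = sum(config.census.values())
    if total > config.grid_area:
        raise ConfigurationError(
            f"census total {total} exceeds grid capacity {config.grid_area}"
        )
    unknown = set(config.census) - set(_MOBILE_TYPES)
    if unknown:
        raise ConfigurationError(f"unknown cell types in census: {sorted(unknown)}")

    capacity = max(4 * total, 16)
    type_code = np.zeros(capacity, dtype=np.int8)
    rows = np.zeros(capacity, dtype=np.int32)
    cols = np.zeros(capacity, dtype=np.int32)
    activation = np.zeros(capacity)
    age = np.zeros(capacity, dtype=np.int32)
    alive = np.zeros(capacity, dtype=bool)

    i = 0
    for cell_type in _MOBILE_TYPES:
        for _ in range(config.census.get(cell_type, 0)):
            type_code[i] = _TYPE_CODE[cell_type]
            rows[i] = rng.integers(h)
            cols[i] = rng.integers(w)
            alive[i] = True
            i += 1

    damage = np.zeros((h, w))
    fields = np.zeros((n_entities, h, w))
    patch = _grow_patch(h, w, config.injury_size, rng)
    damage[patch] = 1.0
    # index 16 is DAMP in the default catalog; initialize() is catalog-agnostic
    # so the release goes to the last entity slot, which the default reserves
    # for the damage signal.
    fields[-1][patch] = config.injury_damp_release

    return WorldState(
        config=config, fields=fields, damage=damage,
        type_code=type_code, rows=rows, cols=cols,
        activation=activation, age=age, alive=alive,
    )


def _diffuse_decay(fields: np.ndarray, diffusion: float, decay: np.ndarray) -> np.ndarray:
    """Explicit 4-neighbor diffusion then multiplicative decay, per entity."""
    up = np.roll(fields, 1, axis=1)
    down = np.roll(fields, -1, axis=1)
    left = np.roll(fields, 1, axis=2)
    right = np.roll(fields, -1, axis=2)
    mean4 = 0.25 * (up + down + left + right)
    out = fields + diffusion * (mean4 - fields)
    out *= (1.0 - decay)[:, None, None]
    return out


def _spawn(world: WorldState, cell_type: str, n: int, rng: np.random.Generator):
    """Reuse dead slots to add n fresh agents at random locations."""
    if n <= 0:
        return
    free = np.flatnonzero(~world.alive)[:n]
    h, w = world.damage.shape
    for slot in free:
        world.type_code[slot] = _TYPE_CODE[cell_type]
        world.rows[slot] = rng.integers(h)
        world.cols[slot] = rng.integers(w)
        world.activation[slot] = 0.0
        world.age[slot] = 0
        world.alive[slot] = True


def step(
    world: WorldState,
    compiled: "_CompiledRules | ModelRuleMatrix",
    rng: np.random.Generator,
) -> WorldState:
    """One synchronous update of agents, fields and movement (in place).

    All drives are read from the pre-step field snapshot and all within-step
    effects commute (secretion is additive, clearance multiplicative, state
    updates touch only the acting agent), so the update has no order bias.
    """
    if isinstance(compiled, ModelRuleMatrix):
        compiled = _CompiledRules(compiled, world.config)
    cfg = world.config
    h, w = world.damage.shape
    F0 = world.fields
    delta = np.zeros_like(F0)
    clear_factor = np.ones_like(F0)

    # --- endothelial rules (vectorized over the whole lattice) -------------
    damage = world.damage
    damage_new = damage.copy()
    endo_idx = compiled.by_owner[cat.ENDOTHELIAL]
    # one tensordot for all endothelial drives: (k, H, W)
    endo_drives = np.tensordot(compiled.weights[endo_idx], F0, axes=(1, 0))
    endo_drives += compiled.bias[endo_idx][:, None, None]
    for k, ri in enumerate(endo_idx):
        g = compiled.response_at(ri, endo_drives[k])
        rule = compiled.rules[ri]
        if rule.target == "damage":
            damage_new += rule.rate * g
        elif rule.target == "heal":
            damage_new -= rule.rate * g
        else:  # secretion scaled by local damage (injured endothelium signals)
            delta[compiled.target_entity[ri]] += rule.rate * g * damage
    np.clip(damage_new, 0.0, 1.0, out=damage_new)

    # --- mobile agents, vectorized per type --------------------------------
    alive = world.alive
    kill = np.zeros_like(alive)
    for cell_type in _MOBILE_TYPES:
        sel = np.flatnonzero(alive & (world.type_code == _TYPE_CODE[cell_type]))
        if sel.size == 0:
            continue
        r_, c_ = world.rows[sel], world.cols[sel]
        C = F0[:, r_, c_].T  # (n, entities)
        act = world.activation[sel]
        diff_done = np.zeros(sel.size, dtype=bool)
        # one matmul for all of this type's rule drives: (n, k)
        drives = C @ compiled.owner_weights[cell_type] + compiled.owner_bias[cell_type]
        for k, ri in enumerate(compiled.by_owner[cell_type]):
            rule = compiled.rules[ri]
            g = compiled.response_at(ri, drives[:, k])
            if rule.family == cat.ACTIVATION:
                act = np.clip(act + rule.rate * (g - act), 0.0, 1.0)
            elif rule.family == cat.UPREGULATION:
                amt = rule.rate * g * act
                np.add.at(delta[compiled.target_entity[ri]], (r_, c_), amt)
            elif rule.family == cat.DOWNREGULATION:
                f = np.clip(1.0 - rule.rate * g * act, 0.0, 1.0)
                np.multiply.at(clear_factor[compiled.target_entity[ri]], (r_, c_), f)
            elif rule.family == cat.DIFFERENTIATION:
                p = np.clip(rule.rate * g, 0.0, 1.0)
                fire = (rng.random(sel.size) < p) & ~diff_done
                if np.any(fire):
                    world.type_code[sel[fire]] = _TYPE_CODE[rule.target]
                    world.activation[sel[fire]] = 0.0
                    world.age[sel[fire]] = 0
                    diff_done |= fire
            elif rule.family == cat.LIFESPAN:
                p = np.clip(rule.rate * g, 0.0, 1.0)
                kill[sel[rng.random(sel.size) < p]] = True
        world.activation[sel] = act
        # senescence
        kill[sel[world.age[sel] > _LIFESPAN[cell_type]]] = True

    world.damage = damage_new
    world.alive &= ~kill
    fields = np.clip((F0 + delta) * clear_factor, 0.0, None)

    # replenish the precursor pool toward its initial census
    target_prec = cfg.census.get(cat.PRECURSOR, 0)
    n_prec = int(np.sum(world.alive & (world.type_code == _TYPE_CODE[cat.PRECURSOR])))
    deficit = target_prec - n_prec
    if deficit > 0:
        _spawn(world, cat.PRECURSOR, int(rng.binomial(deficit, 0.2)), rng)

    # --- diffusion and decay ------------------------------------------------
    if compiled.decay is not None:
        decay = compiled.decay
    else:
        decay = np.full(compiled.n_entities, cfg.decay)
        for name, value in cfg.decay_overrides.items():
            try:
                decay[compiled.mrm.entities.index(name)] = value
            except ValueError:
                pass
    world.fields = _diffuse_decay(fields, cfg.diffusion, decay)

    # --- movement: chemotaxis toward DAMP + IL-8, else random walk ----------
    attract = world.fields[compiled.damp_idx] + world.fields[compiled.il8_idx]
    moving = np.flatnonzero(world.alive)
    if moving.size:
        r_, c_ = world.rows[moving], world.cols[moving]
        cand_r = np.stack([r_, (r_ - 1) % h, (r_ + 1) % h, r_, r_])
        cand_c = np.stack([c_, c_, c_, (c_ - 1) % w, (c_ + 1) % w])
        vals = attract[cand_r, cand_c]          # (5, n): stay + 4 neighbors
        best = np.argmax(vals[1:], axis=0) + 1
        gain = vals[best, np.arange(moving.size)] - vals[0]
        random_dir = rng.integers(0, 5, size=moving.size)
        choice = np.where(gain > cfg.chemotaxis_threshold, best, random_dir)
        world.rows[moving] = cand_r[choice, np.arange(moving.size)]
        world.cols[moving] = cand_c[choice, np.arange(moving.size)]

    world.age[world.alive] += 1
    world.t += 1
    return world


def run_simulation(
    config: SimulationConfig,
    mrm: ModelRuleMatrix,
    seed: int | None = None,
    mrm_id: str = "",
) -> Trajectory:
    """Run one full simulation and classify its outcome.

    The run truncates when health falls to the death threshold. Terminal
    health at or above the resolve threshold classifies as resolved; below it
    (but above death) as persistent inflammation.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    world = initialize(config, rng, n_entities=len(mrm.entities))
    compiled = _CompiledRules(mrm, config)

    times, values, health = [0], [world.mediator_aggregates()], [world.health]
    outcome = None
    for t in range(1, config.duration + 1):
        step(world, compiled, rng)
        if t % config.sampling_interval == 0:
            times.append(t)
            values.append(world.mediator_aggregates())
            health.append(world.health)
        if world.health <= config.death_threshold:
            if t % config.sampling_interval != 0:
                times.append(t)
                values.append(world.mediator_aggregates())
                health.append(world.health)
            outcome = DEAD
            break
    if outcome is None:
        outcome = RESOLVED if world.health >= config.resolve_threshold else PERSISTENT
    return Trajectory(
        times=np.array(times),
        values=np.stack(values),
        health=np.array(health),
        outcome=outcome,
        seed=seed,
        mrm_id=mrm_id,
    )


def save_trajectory(
    traj: Trajectory,
    entities,
    path_prefix: str,
    run_id: str = "run",
) -> tuple[str, str]:
    """Write one trajectory as long CSV plus a JSON sidecar.

    The CSV has columns (run_id, mrm_id, seed, time, entity, value); the
    sidecar carries the outcome, the health series and provenance.
    """
    import csv
    import json

    csv_path = path_prefix + ".csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["run_id", "mrm_id", "seed", "time", "entity", "value"])
        for ti, t in enumerate(traj.times):
            for j, name in enumerate(entities.names):
                writer.writerow([run_id, traj.mrm_id, traj.seed, int(t),
                                 name, repr(float(traj.values[ti, j]))])
    sidecar_path = path_prefix + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump({
            "run_id": run_id,
            "outcome": traj.outcome,
            "seed": traj.seed,
            "mrm_id": traj.mrm_id,
            "times": [int(t) for t in traj.times],
            "health": [float(h) for h in traj.health],
        }, fh)
    return csv_path, sidecar_path


def replicate_seed(base_seed: int, index: int) -> int:
    """Stable per-replicate seed; index i always maps to the same seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicates(
    config: SimulationConfig,
    mrm: ModelRuleMatrix,
    n: int,
    base_seed: int | None = None,
    mrm_id: str = "",
    injury_range: tuple[int, int] | None = None,
) -> TrajectorySpace:
    """n seeded replicate runs plus their per-time per-entity min/max envelope.

    Replicate i uses a seed derived from (base_seed, i), so the replicate set
    for n=8 is a prefix of the set for n=64 under the same base seed. When
    ``injury_range`` is given, replicate injury sizes span it evenly —
    one parameterization responding to the spread of insults a cohort
    represents — so the envelope reflects both intrinsic stochasticity and
    insult heterogeneity.
    """
    if n < 1:
        raise ParameterError(f"replicate count must be >= 1, got {n}")
    base_seed = config.seed if base_seed is None else base_seed
    if injury_range is None:
        injuries = [config.injury_size] * n
    else:
        lo, hi = injury_range
        injuries = [int(round(lo + (hi - lo) * i / max(n - 1, 1))) for i in range(n)]
    reps = []
    for i in range(n):
        cfg = config
        if injuries[i] != config.injury_size:
            cfg = SimulationConfig(**{**config.__dict__, "injury_size": injuries[i]})
        reps.append(
            run_simulation(cfg, mrm, seed=replicate_seed(base_seed, i), mrm_id=mrm_id)
        )
    all_times = np.unique(np.concatenate([r.times for r in reps]))
    n_ent = reps[0].values.shape[1]
    env_min = np.full((all_times.size, n_ent), np.inf)
    env_max = np.full((all_times.size, n_ent), -np.inf)
    for r in reps:
        pos = np.searchsorted(all_times, r.times)
        env_min[pos] = np.minimum(env_min[pos], r.values)
        env_max[pos] = np.maximum(env_max[pos], r.values)
    return TrajectorySpace(
        replicates=reps,
        envelope_times=all_times,
        envelope_min=env_min,
        envelope_max=env_max,
    )
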