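"""GA + active-learning calibration to the set of non-falsifiable MRMs.

Calibration here inverts the usual fitting goal: instead of one best-fit
parameterization, it seeks the *entire set* of Model Rule Matrices whose
stochastic replicate output cannot be rejected by the sparse observation
envelopes. A genetic algorithm evolves enriched MRMs toward full envelope
coverage; an active-learning loop then maps the boundary of the
non-falsifiable region by repeatedly simulating the candidates a surrogate
classifier is least certain about. The result is a valid ensemble whose
per-element value ranges (the range matrix) characterize how far each
interaction coefficient can move before the data rejects it.

Falsification is interval intersection per time bin: a candidate survives a
(cohort, entity, bin) constraint iff the min/max band of its replicate
aggregates overlaps the observation envelope there. Intersection (rather than
containment) is the weakest criterion that still rejects, which keeps the
retained set maximally expansive; strict containment is available as a
switch.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .abm import run_replicates
from .config import ALConfig, GAConfig, SimulationConfig, spawn_seed
from .errors import CalibrationError, ParameterError
from .mrm import (
    ModelRuleMatrix,
    RangeMatrix,
    crossover,
    deserialize_mrm,
    element_ranges,
    mutate,
    serialize_mrm,
)
from .reference import Envelope

NON_FALSIFIED = "non-falsified"
FALSIFIED = "falsified"

INTERSECT = "intersect"
CONTAIN = "contain"


@dataclass
class FalsificationReport:
    """Outcome of testing one MRM against one cohort's envelope."""

    verdict: str
    coverage: dict              # (entity, bin_start) -> bool
    coverage_fraction: float
    violations: list            # (entity, bin_start, sim_band, envelope_band)
    n_replicates: int
    seed: int

    @property
    def non_falsified(self) -> bool:
        return self.verdict == NON_FALSIFIED


@dataclass
class EnsembleMember:
    """A non-falsified MRM with its provenance."""

    mrm: ModelRuleMatrix
    cohort: str
    fitness: float
    stage: str                  # "ga" or "al"
    round: int
    eval_seed: int
    member_id: str = ""


@dataclass
class ValidEnsemble:
    """All non-falsified MRMs found by calibration, plus their range matrix."""

    members: list[EnsembleMember]
    range_matrix: RangeMatrix

    def __post_init__(self):
        if not self.members:
            raise CalibrationError("a valid ensemble cannot be empty")

    def __len__(self) -> int:
        return len(self.members)

    def mrms(self) -> list[ModelRuleMatrix]:
        return [m.mrm for m in self.members]

    @property
    def cohorts(self) -> tuple[str, ...]:
        return tuple(sorted({m.cohort for m in self.members}))

    def for_cohort(self, cohort: str) -> list[EnsembleMember]:
        return [m for m in self.members if m.cohort == cohort]


def falsify(
    mrm: ModelRuleMatrix,
    envelope: Envelope,
    cohort: str,
    sim_config: SimulationConfig,
    n_replicates: int = 2,
    seed: int = 0,
    criterion: str = INTERSECT,
    injury_range: tuple[int, int] | None = None,
) -> FalsificationReport:
    """Test one MRM against one cohort's envelope with replicate simulations.

    For each constrained (entity, bin): the simulated band is the min/max of
    the grid-mean aggregate over every replicate sample whose time maps into
    the bin. Under ``intersect`` the bin is covered iff the band overlaps the
    envelope interval; under ``contain`` the band must lie inside it. A bin
    the simulation never reaches (e.g., after an early death truncation)
    counts as uncovered. Verdict is non-falsified iff every bin is covered.
    """
    if n_replicates < 2:
        raise ParameterError("falsification needs at least 2 replicates")
    constraints = envelope.constrained_bins(cohort)
    if not constraints:
        raise ParameterError(
            f"no constrained bins for cohort {cohort!r}; vacuous falsification refused"
        )
    if criterion not in (INTERSECT, CONTAIN):
        raise ParameterError(f"unknown criterion {criterion!r}")

    space = run_replicates(sim_config, mrm, n_replicates, base_seed=seed,
                           injury_range=injury_range)
    ent_index = {name: i for i, name in enumerate(mrm.entities.names)}
    days = space.envelope_times / sim_config.steps_per_day
    bin_of = np.floor(days / envelope.bin_width) * envelope.bin_width

    coverage, violations = {}, []
    for entity, bin_start, lo, hi in constraints:
        j = ent_index.get(entity)
        if j is None:
            coverage[(entity, bin_start)] = False
            violations.append((entity, bin_start, None, (lo, hi)))
            continue
        in_bin = bin_of == bin_start
        if not np.any(in_bin):
            coverage[(entity, bin_start)] = False
            violations.append((entity, bin_start, None, (lo, hi)))
            continue
        smin = float(np.min(space.envelope_min[in_bin, j]))
        smax = float(np.max(space.envelope_max[in_bin, j]))
        if criterion == INTERSECT:
            covered = (smax >= lo) and (smin <= hi)
        else:
            covered = (smin >= lo) and (smax <= hi)
        coverage[(entity, bin_start)] = covered
        if not covered:
            violations.append((entity, bin_start, (smin, smax), (lo, hi)))

    frac = sum(coverage.values()) / len(coverage)
    verdict = NON_FALSIFIED if frac == 1.0 else FALSIFIED
    return FalsificationReport(
        verdict=verdict,
        coverage=coverage,
        coverage_fraction=frac,
        violations=violations,
        n_replicates=n_replicates,
        seed=seed,
    )


@dataclass
class Candidate:
    """One evaluated MRM with its fitness record."""

    mrm: ModelRuleMatrix
    fitness: float              # mean coverage fraction over evaluated cohorts
    n_violations: int
    deviation: float            # L1 distance from the base MRM
    non_falsified: bool         # non-falsified for every evaluated cohort
    generation: int
    eval_seed: int
    # entity -> +1 (simulated band above envelope) / -1 (below); guides
    # repair mutations
    violation_sides: dict = field(default_factory=dict)

    def key(self) -> tuple:
        """Sort key: coverage first, then fewer violations, then closer to base."""
        return (self.fitness, -self.n_violations, -self.deviation)


def _evaluate(
    mrm: ModelRuleMatrix,
    base: ModelRuleMatrix,
    envelope: Envelope,
    cohorts: list[str],
    sim_config: SimulationConfig,
    n_replicates: int,
    eval_seed: int,
    generation: int,
    criterion: str = INTERSECT,
    injury_ranges: dict | None = None,
) -> Candidate:
    fracs, violations, ok = [], 0, True
    sides: dict = {}
    for cohort in cohorts:
        rng_inj = (injury_ranges or {}).get(cohort)
        rep = falsify(mrm, envelope, cohort, sim_config, n_replicates,
                      seed=eval_seed, criterion=criterion, injury_range=rng_inj)
        fracs.append(rep.coverage_fraction)
        violations += len(rep.violations)
        ok &= rep.non_falsified
        for entity, _bin, sim_band, (lo, hi) in rep.violations:
            if sim_band is None:
                continue
            if sim_band[0] > hi:
                sides[entity] = 1       # overproduced relative to the data
            elif sim_band[1] < lo:
                sides[entity] = -1      # underproduced
    return Candidate(
        mrm=mrm,
        fitness=float(np.mean(fracs)),
        n_violations=violations,
        deviation=float(np.abs(mrm.values - base.values).sum()),
        non_falsified=ok,
        generation=generation,
        eval_seed=eval_seed,
        violation_sides=sides,
    )


def ga_search(
    base: ModelRuleMatrix,
    envelope: Envelope,
    cohorts: list[str] | str,
    ga: GAConfig,
    sim_config: SimulationConfig,
    criterion: str = INTERSECT,
    injury_ranges: dict | None = None,
) -> list[Candidate]:
    """Evolve enriched MRMs from the base toward full envelope coverage.

    The initial population consists of mutants of the base MRM (mutation may
    flip latent zeros to nonzero — the enrichment move). Selection is by
    fitness (mean coverage fraction over the given cohorts), ties broken
    toward fewer violations then smaller deviation from base; elites are
    carried with cached fitness, so best fitness is non-decreasing. The search
    returns every evaluated candidate and stops early once an elite reaches
    full coverage, since coverage cannot exceed 1.
    """
    cohorts = [cohorts] if isinstance(cohorts, str) else list(cohorts)
    for cohort in cohorts:
        if not envelope.constrained_bins(cohort):
            raise CalibrationError(f"envelope has no constraints for cohort {cohort!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=ga.seed, spawn_key=(0,)))

    def eval_seed(counter: int) -> int:
        return spawn_seed(ga.seed, 1, counter)

    # entity -> rows of rules secreting it; concentrations are nonnegative,
    # so shifting any coefficient of a secretion rule moves that entity's
    # output monotonically — the structural hint behind repair mutations
    secretion_rows: dict[str, list[int]] = {}
    for ri, rule in enumerate(base.rules.rules):
        if rule.family == "cytokine-upregulation":
            secretion_rows.setdefault(rule.target, []).append(ri)

    def repair(mrm: ModelRuleMatrix, sides: dict) -> ModelRuleMatrix:
        """Move a secretion rule of one violated entity in the corrective
        direction: damp the row toward zero when overproduced; when
        underproduced, pull the row back toward the base row (which does
        produce) or bump a coefficient — a saturated clipped response gives
        no incremental signal, so the row-level move is what escapes the
        dead zone."""
        entities = [e for e in sides if e in secretion_rows]
        if not entities:
            return mrm
        entity = entities[int(rng.integers(len(entities)))]
        row = secretion_rows[entity][int(rng.integers(len(secretion_rows[entity])))]
        values = mrm.values.copy()
        if sides[entity] > 0:  # overproduced: damp the whole drive
            values[row] *= rng.uniform(0.0, 0.8)
        else:                  # underproduced
            t = rng.uniform(0.3, 1.0)
            if np.allclose(values[row], base.values[row], atol=0.1):
                cols = rng.choice(values.shape[1],
                                  size=int(rng.integers(1, 3)), replace=False)
                values[row, cols] += rng.uniform(0.2, 1.0, size=cols.size)
            else:
                values[row] += t * (base.values[row] - values[row])
        return mrm.copy_with(np.clip(values, *mrm.bounds))

    counter = 0
    population: list[Candidate] = []
    for i in range(ga.population_size):
        # seed the population with the incumbent base model itself, then mutants
        m = base if i == 0 else mutate(base, ga.mutation_rate, ga.mutation_scale, rng)
        population.append(
            _evaluate(m, base, envelope, cohorts, sim_config,
                      ga.replicates_per_eval, eval_seed(counter), 0, criterion,
                      injury_ranges)
        )
        counter += 1

    evaluated = list(population)
    for gen in range(1, ga.generations):
        population.sort(key=Candidate.key, reverse=True)
        # stop once coverage is solved AND enough diverse valid candidates
        # exist to seed boundary mapping
        n_valid = sum(c.non_falsified for c in evaluated)
        if population[0].fitness >= 1.0 and n_valid >= ga.population_size // 2:
            break
        elites = population[: ga.elite_count]
        offspring: list[Candidate] = []
        n_children = ga.population_size - len(elites)
        for _ in range(n_children):
            # binary tournament selection
            i, j = rng.integers(len(population), size=2)
            pa = max(population[i], population[j], key=Candidate.key)
            i, j = rng.integers(len(population), size=2)
            pb = max(population[i], population[j], key=Candidate.key)
            child = crossover(pa.mrm, pb.mrm, rng)
            # half the children receive a violation-guided repair move;
            # heavy-tailed mutation scales let the rest escape plateaus
            if pa.violation_sides and rng.random() < 0.5:
                child = repair(child, pa.violation_sides)
            scale = ga.mutation_scale * float(rng.choice([1.0, 2.0, 4.0]))
            child = mutate(child, ga.mutation_rate, scale, rng)
            offspring.append(
                _evaluate(child, base, envelope, cohorts, sim_config,
                          ga.replicates_per_eval, eval_seed(counter), gen,
                          criterion, injury_ranges)
            )
            counter += 1
        population = elites + offspring
        evaluated.extend(offspring)

    if all(c.fitness == 0.0 for c in evaluated):
        raise CalibrationError(
            "degenerate envelope: no candidate covers any bin; calibration failed"
        )
    return evaluated


def al_refine(
    seed_candidates: list[Candidate],
    envelope: Envelope,
    cohorts: list[str] | str,
    al: ALConfig,
    sim_config: SimulationConfig,
    base: ModelRuleMatrix | None = None,
    criterion: str = INTERSECT,
    cohort_tag: str = "",
    ga_replicates: int = 2,
    injury_ranges: dict | None = None,
) -> ValidEnsemble:
    """Map the non-falsifiable boundary by uncertainty-driven simulation.

    Each round fits a probabilistic surrogate (an ensemble-of-trees
    classifier) on flattened MRM vectors labeled by their falsification
    verdicts, proposes a pool of bounded uniform perturbations of current
    valid members, simulates the batch the surrogate is least certain about
    (|p - 0.5| minimal), and adds the labels. Stops after ``rounds`` rounds or
    when the ensemble range matrix changes by less than ``stop_tolerance``
    elementwise over a round. Returns every non-falsified member observed.
    """
    cohorts = [cohorts] if isinstance(cohorts, str) else list(cohorts)
    labels = {True: [c for c in seed_candidates if c.non_falsified],
              False: [c for c in seed_candidates if not c.non_falsified]}
    if not labels[True] or not labels[False]:
        raise CalibrationError(
            "active learning needs both non-falsified and falsified seed candidates; "
            "widen the GA search"
        )
    base = base or seed_candidates[0].mrm
    rng = np.random.default_rng(np.random.SeedSequence(entropy=al.seed, spawn_key=(2,)))

    X = [c.mrm.values.ravel() for c in seed_candidates]
    y = [c.non_falsified for c in seed_candidates]
    valid: list[Candidate] = list(labels[True])
    counter = 0
    prev_rm = element_ranges([c.mrm for c in valid])
    n_el = base.values.size
    lo_b, hi_b = base.bounds
    # probes touch few elements at a time (diffuse large perturbations are
    # almost always falsified); stratified selection keeps per-element probe
    # counts even so every coefficient's attainable range gets mapped
    probe_counts = np.zeros(n_el)
    k = max(1, int(round(al.perturb_rate * n_el)))
    ens_min = np.min([c.mrm.values.ravel() for c in valid], axis=0)
    ens_max = np.max([c.mrm.values.ravel() for c in valid], axis=0)
    for round_idx in range(1, al.rounds + 1):
        surrogate = RandomForestClassifier(
            n_estimators=al.surrogate_trees,
            random_state=spawn_seed(al.seed, 3, round_idx),
        )
        surrogate.fit(np.array(X), np.array(y))
        pool, pool_idx = [], []
        by_dev = sorted(valid, key=lambda c: c.deviation)
        near_base = by_dev[: max(1, len(by_dev) // 4)]
        for _ in range(al.pool_size):
            # half the probes start from near-base parents: coefficient
            # tolerances measured there are not confounded by drift elsewhere
            if rng.random() < 0.5:
                parent = near_base[int(rng.integers(len(near_base)))]
            else:
                parent = valid[int(rng.integers(len(valid)))]
            idx = np.argsort(probe_counts + rng.random(n_el))[:k]
            vals = parent.mrm.values.ravel().copy()
            # boundary probe: jump outward past the ensemble's current extreme
            # at each probed element; probes inside the mapped range are wasted
            direction = rng.random(k) < 0.5
            jump = rng.uniform(0.0, al.perturb_scale, size=k)
            vals[idx] = np.where(direction, ens_max[idx] + jump, ens_min[idx] - jump)
            vals = np.clip(vals, lo_b, hi_b).reshape(base.values.shape)
            pool.append(parent.mrm.copy_with(vals))
            pool_idx.append(idx)
        probs = surrogate.predict_proba(np.array([m.values.ravel() for m in pool]))
        p_valid = probs[:, list(surrogate.classes_).index(True)]
        order = np.argsort(np.abs(p_valid - 0.5))
        for i in order[: al.batch_size]:
            m = pool[i]
            probe_counts[pool_idx[i]] += 1
            cand = _evaluate(m, base, envelope, cohorts, sim_config,
                             ga_replicates, spawn_seed(al.seed, 4, counter),
                             round_idx, criterion, injury_ranges)
            counter += 1
            X.append(m.values.ravel())
            y.append(cand.non_falsified)
            if cand.non_falsified:
                valid.append(cand)
                flat = m.values.ravel()
                ens_min = np.minimum(ens_min, flat)
                ens_max = np.maximum(ens_max, flat)
        rm = element_ranges([c.mrm for c in valid])
        if rm.max_change(prev_rm) < al.stop_tolerance:
            prev_rm = rm
            break
        prev_rm = rm

    members = [
        EnsembleMember(
            mrm=c.mrm, cohort=cohort_tag, fitness=c.fitness,
            stage="al" if c.generation > 0 and c not in seed_candidates else "ga",
            round=c.generation, eval_seed=c.eval_seed,
            member_id=f"{cohort_tag}-{k:04d}",
        )
        for k, c in enumerate(valid)
    ]
    return ValidEnsemble(members=members, range_matrix=prev_rm)


def calibrate(
    base: ModelRuleMatrix,
    envelope: Envelope,
    ga: GAConfig,
    al: ALConfig,
    sim_config: SimulationConfig,
    criterion: str = INTERSECT,
    injury_ranges: dict | None = None,
) -> ValidEnsemble:
    """Full per-cohort pipeline: GA enrichment then AL boundary mapping.

    Each candidate is evaluated against a single cohort's envelope and the
    resulting members carry that cohort's tag (an MRM is "cohort-B-type" if it
    survives cohort B's data), mirroring separately parameterized trajectory
    spaces per outcome group. Per-cohort ensembles are merged; the combined
    range matrix spans all members.
    """
    all_members: list[EnsembleMember] = []
    for k, cohort in enumerate(envelope.cohorts):
        al_cfg = ALConfig(**{**al.__dict__, "seed": spawn_seed(al.seed, 11, k)})
        candidates: list[Candidate] = []
        for attempt in range(3):  # fresh-seed restarts ride out hard draws
            ga_cfg = GAConfig(**{**ga.__dict__,
                                 "seed": spawn_seed(ga.seed, 10, k, attempt)})
            candidates.extend(
                ga_search(base, envelope, cohort, ga_cfg, sim_config,
                          criterion, injury_ranges))
            if any(c.non_falsified for c in candidates):
                break
        if not any(c.non_falsified for c in candidates):
            raise CalibrationError(
                f"GA found no non-falsified candidate for cohort {cohort!r}"
            )
        if all(c.non_falsified for c in candidates):
            # boundary mapping needs a negative class; label the worst-coverage
            # extreme mutants by evaluating stronger perturbations
            rng = np.random.default_rng(spawn_seed(al_cfg.seed, 12, k))
            extra = []
            for i in range(al_cfg.batch_size):
                m = mutate(base, 0.5, 2.0, rng)
                extra.append(
                    _evaluate(m, base, envelope, [cohort], sim_config,
                              ga_cfg.replicates_per_eval,
                              spawn_seed(al_cfg.seed, 13, i), 0, criterion,
                              injury_ranges)
                )
            candidates = candidates + extra
        if not any(not c.non_falsified for c in candidates):
            ensemble_members = [
                EnsembleMember(
                    mrm=c.mrm, cohort=cohort, fitness=c.fitness, stage="ga",
                    round=c.generation, eval_seed=c.eval_seed,
                    member_id=f"{cohort}-{i:04d}",
                )
                for i, c in enumerate(candidates) if c.non_falsified
            ]
            all_members.extend(ensemble_members)
            continue
        ens = al_refine(candidates, envelope, cohort, al_cfg, sim_config,
                        base=base, criterion=criterion, cohort_tag=cohort,
                        ga_replicates=ga_cfg.replicates_per_eval,
                        injury_ranges=injury_ranges)
        all_members.extend(ens.members)
    if not all_members:
        raise CalibrationError("calibration produced an empty ensemble")
    return ValidEnsemble(
        members=all_members,
        range_matrix=element_ranges([m.mrm for m in all_members]),
    )


@dataclass
class RecoverySummary:
    """How well the valid ensemble brackets hidden ground-truth MRMs."""

    containment_all: list[float]        # per hidden MRM, fraction over all elements
    containment_perturbed: list[float]  # fraction over declared-perturbed elements
    hidden_non_falsified: list[bool]


def recover_parameters_check(
    hidden_truth,
    ensemble: ValidEnsemble,
    envelope: Envelope | None = None,
    sim_config: SimulationConfig | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    injury_ranges: dict | None = None,
) -> RecoverySummary:
    """Report, per hidden MRM, how much of it the ensemble ranges bracket.

    An element is contained if the hidden value lies within the ensemble's
    [min, max] at that element. If an envelope and simulation config are
    supplied, each hidden MRM is additionally re-tested for falsification
    against its own cohort's envelope.
    """
    stack = np.stack([m.values for m in ensemble.mrms()])
    ens_min, ens_max = stack.min(axis=0), stack.max(axis=0)
    tol = 1e-12
    containment_all, containment_perturbed, verdicts = [], [], []
    for cohort, hidden in hidden_truth.mrms:
        inside = (hidden.values >= ens_min - tol) & (hidden.values <= ens_max + tol)
        containment_all.append(float(inside.mean()))
        pe = hidden_truth.perturbed_elements
        containment_perturbed.append(
            float(np.mean([inside[i, j] for (i, j) in pe])) if pe else 1.0
        )
        if envelope is not None and sim_config is not None:
            rep = falsify(hidden, envelope, cohort, sim_config, n_replicates,
                          seed=seed,
                          injury_range=(injury_ranges or {}).get(cohort))
            verdicts.append(rep.non_falsified)
    return RecoverySummary(
        containment_all=containment_all,
        containment_perturbed=containment_perturbed,
        hidden_non_falsified=verdicts,
    )


# -- ensemble archive --------------------------------------------------------

def save_ensemble(ensemble: ValidEnsemble, directory: str) -> None:
    """Write member MRM JSONs, a manifest, and the range matrix."""
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for m in ensemble.members:
        fname = f"{m.member_id or id(m)}.json"
        with open(os.path.join(directory, fname), "w") as fh:
            fh.write(serialize_mrm(m.mrm))
        manifest.append({
            "file": fname, "member_id": m.member_id, "cohort": m.cohort,
            "fitness": m.fitness, "stage": m.stage, "round": m.round,
            "eval_seed": m.eval_seed,
        })
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump({"members": manifest}, fh, indent=1)
    with open(os.path.join(directory, "range_matrix.json"), "w") as fh:
        json.dump({"ranges": ensemble.range_matrix.ranges.tolist()}, fh)


def load_ensemble(directory: str) -> ValidEnsemble:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)["members"]
    members = []
    for entry in manifest:
        with open(os.path.join(directory, entry["file"])) as fh:
            mrm = deserialize_mrm(fh.read())
        members.append(EnsembleMember(
            mrm=mrm, cohort=entry["cohort"], fitness=entry["fitness"],
            stage=entry["stage"], round=entry["round"],
            eval_seed=entry["eval_seed"], member_id=entry["member_id"],
        ))
    return ValidEnsemble(
        members=members,
        range_matrix=element_ranges([m.mrm for m in members]),
    )
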