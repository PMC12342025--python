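"""Falsification, GA enrichment, AL boundary mapping, recovery checks."""

import numpy as np
import pandas as pd
import pytest

from smtgen import (
    ALConfig,
    GAConfig,
    ReferenceDataset,
    al_refine,
    build_envelope,
    calibrate,
    element_ranges,
    falsify,
    ga_search,
    mutate,
    recover_parameters_check,
    run_replicates,
)
from smtgen.calibration import (
    Candidate,
    EnsembleMember,
    ValidEnsemble,
    load_ensemble,
    save_ensemble,
)
from smtgen.errors import CalibrationError, ParameterError
from smtgen.reference import Envelope

from conftest import mini_sim_config


def trajectories_to_dataset(space, entities, steps_per_day, cohort="A"):
    """Turn replicate trajectories into a dense observation table."""
    rows = []
    obs = entities.observed_names
    idx = list(entities.observed_subset)
    for r, traj in enumerate(space.replicates):
        for ti, t in enumerate(traj.times):
            for name, j in zip(obs, idx):
                rows.append((f"r{r}", cohort, t / steps_per_day, name,
                             float(traj.values[ti, j])))
    return ReferenceDataset(pd.DataFrame(
        rows, columns=["subject_id", "cohort", "time", "entity", "value"]))


@pytest.fixture(scope="module")
def mini_envelope(mini_reference):
    _, dataset, _ = mini_reference
    return build_envelope(dataset, bin_width=1.0, alpha=1.0)


@pytest.fixture(scope="module")
def injury_ranges(mini_reference):
    cfg, _, _ = mini_reference
    return cfg.injury_range


class TestFalsify:
    def test_self_consistency(self, base_mrm, mini_sim):
        """An MRM is never falsified by the envelope of its own outputs."""
        space = run_replicates(mini_sim, base_mrm, 4, base_seed=50)
        ds = trajectories_to_dataset(space, base_mrm.entities, mini_sim.steps_per_day)
        env = build_envelope(ds, bin_width=1.0, alpha=1.0)
        rep = falsify(base_mrm, env, "A", mini_sim, n_replicates=2, seed=50)
        assert rep.non_falsified
        assert rep.coverage_fraction == 1.0

    def test_unreachable_bin_falsifies_and_is_flagged(self, base_mrm, mini_sim):
        """An envelope interval above anything a zero-secretion entity can
        reach must falsify, flagging exactly that bin."""
        zeroed = base_mrm.copy_with(base_mrm.values.copy())
        row = base_mrm.rules.index("th1-secrete-IFNg")
        zeroed.values[row, :] = 0.0
        env = Envelope(
            bounds={"A": {"IFNg": {0.0: (50.0, 60.0)},
                          "TNFa": {0.0: (0.0, 1e9)}}},
            bin_width=1.0, alpha=1.0,
        )
        rep = falsify(zeroed, env, "A", mini_sim, n_replicates=2, seed=1)
        assert not rep.non_falsified
        assert rep.coverage[("IFNg", 0.0)] is False
        assert rep.coverage[("TNFa", 0.0)] is True

    def test_coverage_nondecreasing_in_alpha(self, base_mrm, mini_sim, mini_reference):
        _, dataset, _ = mini_reference
        fracs = []
        for alpha in (1.0, 1.5, 2.5):
            env = build_envelope(dataset, 1.0, alpha=alpha)
            rep = falsify(base_mrm, env, "A", mini_sim, n_replicates=2, seed=5)
            fracs.append(rep.coverage_fraction)
        assert fracs == sorted(fracs)

    def test_too_few_replicates_rejected(self, base_mrm, mini_sim, mini_envelope):
        with pytest.raises(ParameterError):
            falsify(base_mrm, mini_envelope, "A", mini_sim, n_replicates=1)

    def test_vacuous_falsification_refused(self, base_mrm, mini_sim, mini_envelope):
        with pytest.raises(ParameterError):
            falsify(base_mrm, mini_envelope, "Z", mini_sim, n_replicates=2)


class TestGASearch:
    def test_clone_population_fixed_point(self, base_mrm, mini_sim):
        """With mutation off, the population is all base clones; against an
        envelope base itself generated (widened for replicate-to-replicate
        spread) every candidate scores full coverage immediately."""
        space = run_replicates(mini_sim, base_mrm, 6, base_seed=50)
        ds = trajectories_to_dataset(space, base_mrm.entities, mini_sim.steps_per_day)
        env = build_envelope(ds, bin_width=1.0, alpha=1.5)
        ga = GAConfig(population_size=4, generations=1, elite_count=1,
                      mutation_rate=0.0, mutation_scale=1.0, seed=1)
        out = ga_search(base_mrm, env, "A", ga, mini_sim)
        assert len(out) == 4
        assert all(c.fitness == 1.0 for c in out)
        assert all(np.array_equal(c.mrm.values, base_mrm.values) for c in out)

    def test_best_fitness_monotone_across_generations(self, base_mrm, mini_sim,
                                                      mini_envelope, injury_ranges):
        ga = GAConfig(population_size=6, generations=4, elite_count=1,
                      mutation_rate=0.08, mutation_scale=0.8, seed=2)
        out = ga_search(base_mrm, mini_envelope, "A", ga, mini_sim,
                        injury_ranges=injury_ranges)
        gens = sorted({c.generation for c in out})
        best_so_far = -np.inf
        for g in gens:
            best_here = max(c.fitness for c in out if c.generation <= g)
            assert best_here >= best_so_far
            best_so_far = best_here

    def test_degenerate_envelope_surfaces_failure(self, base_mrm, mini_sim):
        env = Envelope(bounds={"A": {"TNFa": {0.0: (1e6, 1e7)}}},
                       bin_width=1.0, alpha=1.0)
        ga = GAConfig(population_size=3, generations=1, elite_count=1, seed=3)
        with pytest.raises(CalibrationError):
            ga_search(base_mrm, env, "A", ga, mini_sim)


def _labeled_seeds(base_mrm, mini_sim, mini_envelope, injury_ranges):
    """A small candidate set with both verdict classes, labeled by real
    falsification runs: base (covers its own data) plus strong mutants."""
    from smtgen.calibration import _evaluate

    seeds = [_evaluate(base_mrm, base_mrm, mini_envelope, ["A"], mini_sim,
                       2, 0, 0, injury_ranges=injury_ranges)]
    rng = np.random.default_rng(4)
    for i in range(6):
        m = mutate(base_mrm, 0.05, 1.2, rng)
        seeds.append(_evaluate(m, base_mrm, mini_envelope, ["A"], mini_sim,
                               2, 100 + i, 0, injury_ranges=injury_ranges))
    if not any(c.non_falsified for c in seeds) or all(c.non_falsified for c in seeds):
        pytest.skip("seed population lacked both verdict classes")
    return seeds


class TestALRefine:
    def test_infinite_tolerance_stops_after_one_round(self, base_mrm, mini_sim,
                                                      mini_envelope, injury_ranges):
        seeds = _labeled_seeds(base_mrm, mini_sim, mini_envelope, injury_ranges)
        al = ALConfig(batch_size=3, pool_size=6, rounds=4,
                      stop_tolerance=np.inf, seed=5)
        ens = al_refine(seeds, mini_envelope, "A", al, mini_sim, base=base_mrm,
                        cohort_tag="A", injury_ranges=injury_ranges)
        assert all(m.round <= 1 for m in ens.members)

    def test_single_class_seeds_rejected(self, base_mrm, mini_sim, mini_envelope):
        good = Candidate(base_mrm, 1.0, 0, 0.0, True, 0, 0)
        al = ALConfig(batch_size=2, pool_size=4, rounds=1, seed=6)
        with pytest.raises(CalibrationError):
            al_refine([good], mini_envelope, "A", al, mini_sim)

    def test_range_matrix_superset_monotonicity(self, base_mrm, mini_sim,
                                                mini_envelope, injury_ranges):
        """The final ensemble's ranges dominate the GA-only valid set's."""
        seeds = _labeled_seeds(base_mrm, mini_sim, mini_envelope, injury_ranges)
        ga_rm = element_ranges([c.mrm for c in seeds if c.non_falsified])
        al = ALConfig(batch_size=4, pool_size=8, rounds=2, seed=7)
        ens = al_refine(seeds, mini_envelope, "A", al, mini_sim, base=base_mrm,
                        cohort_tag="A", injury_ranges=injury_ranges)
        assert np.all(ens.range_matrix.ranges >= ga_rm.ranges - 1e-12)


class TestRecovery:
    def test_ensemble_containing_hidden_has_full_containment(self, base_mrm,
                                                             mini_reference):
        _, _, truth = mini_reference
        members = [
            EnsembleMember(mrm=m, cohort=c, fitness=1.0, stage="ga", round=0,
                           eval_seed=0, member_id=f"{c}-{i}")
            for i, (c, m) in enumerate(truth.mrms)
        ]
        ens = ValidEnsemble(members=members,
                            range_matrix=element_ranges([m.mrm for m in members]))
        rec = recover_parameters_check(truth, ens)
        assert rec.containment_all == [1.0] * len(truth.mrms)
        assert rec.containment_perturbed == [1.0] * len(truth.mrms)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(CalibrationError):
            ValidEnsemble(members=[], range_matrix=None)


class TestArchive:
    def test_save_load_round_trip(self, tmp_path, base_mrm, rng):
        members = [
            EnsembleMember(mrm=mutate(base_mrm, 0.1, 0.5, rng), cohort="A",
                           fitness=1.0, stage="al", round=i, eval_seed=i,
                           member_id=f"A-{i:04d}")
            for i in range(3)
        ]
        ens = ValidEnsemble(members=members,
                            range_matrix=element_ranges([m.mrm for m in members]))
        save_ensemble(ens, str(tmp_path / "arch"))
        back = load_ensemble(str(tmp_path / "arch"))
        assert len(back) == 3
        for a, b in zip(ens.members, back.members):
            assert a.member_id == b.member_id and a.cohort == b.cohort
            assert np.allclose(a.mrm.values, b.mrm.values, atol=1e-10)
        assert np.allclose(back.range_matrix.ranges, ens.range_matrix.ranges,
                           atol=1e-10)
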