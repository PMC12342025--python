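"""Agent-based simulator: determinism, conservation, injury response."""

import numpy as np
import pytest
from scipy import stats

from smtgen import build_base_mrm, initialize, run_replicates, run_simulation
from smtgen.abm import RESOLVED, replicate_seed
from smtgen.catalogs import (
    RuleCatalog,
    RuleDescriptor,
    default_entity_catalog,
    default_rule_catalog,
)
from smtgen.errors import ConfigurationError, ParameterError

from conftest import mini_sim_config


class TestInitialize:
    def test_no_injury_means_full_health(self, base_mrm):
        cfg = mini_sim_config(injury_size=0)
        world = initialize(cfg, np.random.default_rng(0))
        assert world.health == 1.0
        assert np.all(world.damage == 0.0)
        assert np.all(world.fields == 0.0)

    def test_same_seed_identical_placement(self, base_mrm):
        cfg = mini_sim_config()
        w1 = initialize(cfg, np.random.default_rng(5))
        w2 = initialize(cfg, np.random.default_rng(5))
        assert np.array_equal(w1.rows, w2.rows)
        assert np.array_equal(w1.cols, w2.cols)
        assert np.array_equal(w1.damage, w2.damage)

    def test_different_seeds_differ(self):
        cfg = mini_sim_config()
        differing = 0
        for s in range(10):
            w1 = initialize(cfg, np.random.default_rng(2 * s))
            w2 = initialize(cfg, np.random.default_rng(2 * s + 1))
            if not (np.array_equal(w1.rows, w2.rows)
                    and np.array_equal(w1.cols, w2.cols)
                    and np.array_equal(w1.damage, w2.damage)):
                differing += 1
        assert differing == 10

    def test_injury_patch_is_contiguous_and_sized(self):
        cfg = mini_sim_config(injury_size=17)
        world = initialize(cfg, np.random.default_rng(3))
        assert int(world.damage.sum()) == 17

    def test_census_exceeding_capacity_rejected(self):
        cfg = mini_sim_config()
        cfg.census = {"macrophage": 101}
        with pytest.raises(ConfigurationError):
            initialize(cfg, np.random.default_rng(0))


class TestRunSimulation:
    def test_zero_mrm_no_injury_stays_silent(self, base_mrm):
        """No sources anywhere: mediator aggregates remain identically zero."""
        zero = base_mrm.copy_with(np.zeros_like(base_mrm.values))
        cfg = mini_sim_config(injury_size=0)
        traj = run_simulation(cfg, zero, seed=1)
        assert np.all(traj.values == 0.0)
        assert np.all(traj.health == 1.0)
        assert traj.outcome == RESOLVED

    def test_no_injury_resolves_with_full_health(self, base_mrm):
        cfg = mini_sim_config(injury_size=0)
        traj = run_simulation(cfg, base_mrm, seed=4)
        assert traj.outcome == RESOLVED
        assert np.all(traj.health == 1.0)

    def test_identical_seed_identical_trajectory(self, base_mrm, mini_sim):
        t1 = run_simulation(mini_sim, base_mrm, seed=9)
        t2 = run_simulation(mini_sim, base_mrm, seed=9)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(t1.health, t2.health)
        assert t1.outcome == t2.outcome

    def test_stochastic_heterogeneity_across_seeds(self, base_mrm, mini_sim):
        trajs = [run_simulation(mini_sim, base_mrm, seed=s) for s in range(20)]
        distinct = {t.values.tobytes() for t in trajs}
        assert len(distinct) >= 2
        assert np.var([t.terminal_health for t in trajs]) > 0

    def test_aggregates_nonnegative(self, base_mrm, mini_sim):
        traj = run_simulation(mini_sim, base_mrm, seed=2)
        assert np.all(traj.values >= 0.0)

    def test_monotone_injury_severity(self, base_mrm):
        """Mean terminal health is non-increasing in injury size (one-sided
        trend test over 30 replicates at 4 injury sizes)."""
        sizes = [5, 30, 60, 90]
        xs, ys = [], []
        for size in sizes:
            cfg = mini_sim_config(injury_size=size)
            for s in range(30):
                xs.append(size)
                ys.append(run_simulation(cfg, base_mrm, seed=s).terminal_health)
        res = stats.linregress(xs, ys)
        assert res.slope < 0
        assert res.pvalue / 2 < 0.05  # one-sided

    def test_mass_decays_without_secretion(self, base_mrm):
        """All secretion silenced but decay on: every field aggregate shrinks
        toward zero after the initial damage-signal release."""
        rules = default_rule_catalog()
        silenced = RuleCatalog(rules=tuple(
            RuleDescriptor(**{**r.__dict__, "rate": 0.0})
            if r.family == "cytokine-upregulation" else r
            for r in rules.rules
        ))
        mrm = build_base_mrm(default_entity_catalog(), silenced)
        cfg = mini_sim_config(injury_size=20, duration=149)
        traj = run_simulation(cfg, mrm, seed=6)
        totals = traj.values.sum(axis=1)
        assert totals[0] > 0  # injury released the damage signal
        assert np.all(np.diff(totals) <= 1e-12)  # no sources: monotone decay
        assert totals[-1] < 0.05 * totals[0]


class TestRunReplicates:
    def test_single_replicate_degenerate_envelope(self, base_mrm, mini_sim):
        space = run_replicates(mini_sim, base_mrm, 1, base_seed=3)
        assert np.array_equal(space.envelope_min, space.envelope_max)
        assert np.array_equal(space.envelope_min, space.replicates[0].values)

    def test_every_replicate_within_envelope(self, base_mrm, mini_sim):
        space = run_replicates(mini_sim, base_mrm, 5, base_seed=8)
        for rep in space.replicates:
            pos = np.searchsorted(space.envelope_times, rep.times)
            assert np.all(rep.values >= space.envelope_min[pos] - 1e-12)
            assert np.all(rep.values <= space.envelope_max[pos] + 1e-12)

    def test_nested_envelope_containment(self, base_mrm, mini_sim):
        """The n=8 envelope is contained in the n=4-extended... i.e. the
        larger replicate set's envelope contains the smaller's (shared seed
        stream prefix)."""
        small = run_replicates(mini_sim, base_mrm, 4, base_seed=13)
        large = run_replicates(mini_sim, base_mrm, 8, base_seed=13)
        pos = np.searchsorted(large.envelope_times, small.envelope_times)
        assert np.all(large.envelope_min[pos] <= small.envelope_min + 1e-12)
        assert np.all(large.envelope_max[pos] >= small.envelope_max - 1e-12)

    def test_replicate_seed_stability(self):
        assert replicate_seed(42, 3) == replicate_seed(42, 3)
        assert replicate_seed(42, 3) != replicate_seed(42, 4)
        assert 0 <= replicate_seed(42, 3) < 2**31

    def test_replicate_count_validated(self, base_mrm, mini_sim):
        with pytest.raises(ParameterError):
            run_replicates(mini_sim, base_mrm, 0)


def test_trajectory_export_round_trip(tmp_path, base_mrm, mini_sim):
    """Long-CSV + sidecar export reloads to the same values and outcome."""
    import json

    import pandas as pd

    traj = run_simulation(mini_sim, base_mrm, seed=5, mrm_id="m0")
    from smtgen.abm import save_trajectory
    csv_path, sidecar_path = save_trajectory(
        traj, base_mrm.entities, str(tmp_path / "t"), run_id="r0")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    assert len(df) == traj.times.size * len(base_mrm.entities)
    wide = df.pivot(index="time", columns="entity", values="value")
    wide = wide[list(base_mrm.entities.names)].sort_index()
    assert np.array_equal(wide.to_numpy(), traj.values)
    sidecar = json.load(open(sidecar_path))
    assert sidecar["outcome"] == traj.outcome
    assert sidecar["health"] == [float(h) for h in traj.health]


def test_positive_self_feedback_secretion_is_nondecreasing():
    """A secretion rule with a positive self-coefficient and no decay drives
    its own product monotonically upward (brute-force check of the
    recurrence in a macrophage-only micro-world)."""
    entities = default_entity_catalog()
    rules = default_rule_catalog()
    # tonic secretion drive (positive bias) so the loop can bootstrap from zero
    boosted = RuleCatalog(rules=tuple(
        RuleDescriptor(**{**r.__dict__, "bias": 0.2})
        if r.name == "mac-secrete-TNFa" else r
        for r in rules.rules
    ))
    mrm = build_base_mrm(entities, boosted)
    values = mrm.values.copy()
    values[boosted.index("mac-secrete-TNFa"), entities.index("TNFa")] = 1.0
    mrm = mrm.copy_with(values)
    cfg = mini_sim_config(
        injury_size=0, duration=10, decay=0.0,
        decay_overrides={},
        census={"macrophage": 4},
    )
    traj = run_simulation(cfg, mrm, seed=0)
    tnf = traj.values[:, entities.index("TNFa")]
    assert np.all(np.diff(tnf) >= -1e-15)
    assert tnf[-1] > 0
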