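"""SMT generation, separation profiles, expansion summaries, exports."""

import hashlib
import os

import numpy as np
import pandas as pd
import pytest

from smtgen import (
    ReferenceDataset,
    compute_separation,
    element_ranges,
    expansion_check,
    export_smt,
    generate_smt,
    load_smt,
    mutate,
)
from smtgen.calibration import EnsembleMember, ValidEnsemble
from smtgen.errors import ParameterError
from smtgen.smt import SMTDataset, SMTTrajectory

from conftest import mini_sim_config


@pytest.fixture(scope="module")
def tiny_ensemble(base_mrm):
    rng = np.random.default_rng(31)
    members = []
    for i, cohort in enumerate(["A", "A", "B", "B"]):
        members.append(EnsembleMember(
            mrm=mutate(base_mrm, 0.05, 0.5, rng), cohort=cohort, fitness=1.0,
            stage="ga", round=0, eval_seed=i, member_id=f"{cohort}-{i:04d}",
        ))
    return ValidEnsemble(members=members,
                         range_matrix=element_ranges([m.mrm for m in members]))


@pytest.fixture(scope="module")
def tiny_smt(tiny_ensemble):
    # toy cadence: 90 dense samples per run, >= 10x the sparse reference
    from smtgen import toy_simulation_config
    sim = toy_simulation_config()
    return generate_smt(tiny_ensemble, per_member_replicates=2, sim_config=sim,
                        master_seed=5,
                        injury_ranges={"A": (8, 14), "B": (16, 26)})


def _hand_dataset(values_a, values_b, n_times=10):
    """Two one-trajectory cohorts with prescribed constant levels."""
    times = np.arange(n_times)
    trajs = []
    for cohort, level in (("A", values_a), ("B", values_b)):
        for r, v in enumerate(level):
            vals = np.full((n_times, 2), v, dtype=float)
            trajs.append(SMTTrajectory(
                run_id=f"{cohort}{r}", mrm_id=f"m{cohort}", cohort=cohort,
                seed=r, outcome="resolved", times=times.copy(), values=vals,
            ))
    ds = SMTDataset(trajectories=trajs, entities=("TNFa", "IL-6"),
                    steps_per_day=1.0, config_hash="x", master_seed=0)
    ds.compute_envelopes()
    return ds


class TestGenerateSMT:
    def test_counting(self, base_mrm):
        ens = ValidEnsemble(
            members=[EnsembleMember(mrm=base_mrm, cohort="A", fitness=1.0,
                                    stage="ga", round=0, eval_seed=0,
                                    member_id="A-0000")],
            range_matrix=element_ranges([base_mrm]),
        )
        ds = generate_smt(ens, 1, mini_sim_config(), master_seed=1)
        assert len(ds.trajectories) == 1

    def test_size_members_times_replicates(self, tiny_smt, tiny_ensemble):
        assert len(tiny_smt.trajectories) == len(tiny_ensemble) * 2

    def test_trajectories_within_cohort_envelope(self, tiny_smt):
        for traj in tiny_smt.trajectories:
            env = tiny_smt.envelopes[traj.cohort]
            pos = np.searchsorted(env["times"], traj.times)
            assert np.all(traj.values >= env["min"][pos] - 1e-12)
            assert np.all(traj.values <= env["max"][pos] + 1e-12)

    def test_label_fidelity(self, tiny_smt, tiny_ensemble):
        tags = {m.member_id: m.cohort for m in tiny_ensemble.members}
        for traj in tiny_smt.trajectories:
            assert traj.cohort == tags[traj.mrm_id]

    def test_empty_or_invalid_inputs_rejected(self, tiny_ensemble):
        with pytest.raises(ParameterError):
            generate_smt(tiny_ensemble, 0, mini_sim_config())

    def test_denser_than_sparse_reference(self, tiny_smt):
        """Dense simulated cadence: at least 10x the sparse clinical-style
        sampling of at most 8 points per subject."""
        for traj in tiny_smt.trajectories:
            assert traj.times.size >= 10 * 8


class TestSeparation:
    def test_identical_cohorts_never_separate(self):
        ds = _hand_dataset([1.0, 2.0], [1.0, 2.0])
        sep = compute_separation(ds)
        assert sep.n_disjoint_regions() == 0
        assert all(f == 1.0 for f in sep.overlap_fraction.values())

    def test_disjoint_bands_full_interval(self):
        ds = _hand_dataset([0.0, 1.0], [2.0, 3.0], n_times=10)
        sep = compute_separation(ds)
        for entity in ds.entities:
            assert sep.disjoint_intervals[entity] == [(0, 9)]
            assert sep.overlap_fraction[entity] == 0.0

    def test_single_cohort_rejected(self):
        ds = _hand_dataset([1.0], [2.0])
        ds.trajectories = [t for t in ds.trajectories if t.cohort == "A"]
        with pytest.raises(ParameterError):
            compute_separation(ds)


class TestExpansion:
    def test_clipped_control_has_zero_extension(self):
        ds = _hand_dataset([1.0, 2.0], [1.5, 2.5])
        ref = ReferenceDataset(pd.DataFrame(
            [("s1", "A", 0.0, "TNFa", 0.5), ("s2", "B", 1.0, "TNFa", 3.0),
             ("s1", "A", 0.0, "IL-6", 0.5), ("s2", "B", 1.0, "IL-6", 3.0)],
            columns=["subject_id", "cohort", "time", "entity", "value"]))
        exp = expansion_check(ds, ref)
        assert exp.expanded_entities() == []

    def test_extension_beyond_reference(self):
        ds = _hand_dataset([0.1, 5.0], [1.0, 2.0])
        ref = ReferenceDataset(pd.DataFrame(
            [("s1", "A", 0.0, "TNFa", 0.5), ("s2", "B", 1.0, "TNFa", 3.0)],
            columns=["subject_id", "cohort", "time", "entity", "value"]))
        exp = expansion_check(ds, ref)
        assert exp.extension_low["TNFa"] == pytest.approx(0.4)
        assert exp.extension_high["TNFa"] == pytest.approx(2.0)

    def test_extensions_nonnegative(self, tiny_smt, mini_reference):
        _, dataset, _ = mini_reference
        exp = expansion_check(tiny_smt, dataset)
        assert all(v >= 0 for v in exp.extension_low.values())
        assert all(v >= 0 for v in exp.extension_high.values())


def _file_hash(path):
    return hashlib.sha256(open(path, "rb").read()).hexdigest()


class TestExport:
    def test_csv_long_round_trip(self, tmp_path, tiny_smt):
        export_smt(tiny_smt, str(tmp_path / "out"), format="csv-long")
        back = load_smt(str(tmp_path / "out"))
        assert len(back.trajectories) == len(tiny_smt.trajectories)
        orig = {t.run_id: t for t in tiny_smt.trajectories}
        for t in back.trajectories:
            o = orig[t.run_id]
            assert t.cohort == o.cohort and t.outcome == o.outcome
            assert np.array_equal(t.times, o.times)
            assert np.allclose(t.values, o.values, atol=0, rtol=0)

    def test_csv_wide_row_count(self, tmp_path, tiny_smt):
        path = export_smt(tiny_smt, str(tmp_path / "wide"), format="csv-wide")
        df = pd.read_csv(path)
        expected = sum(t.times.size for t in tiny_smt.trajectories)
        assert len(df) == expected
        assert set(tiny_smt.entities) <= set(df.columns)

    def test_rerun_is_byte_identical(self, tmp_path, tiny_ensemble):
        sim = mini_sim_config()
        h = []
        for d in ("a", "b"):
            ds = generate_smt(tiny_ensemble, 2, sim, master_seed=5)
            path = export_smt(ds, str(tmp_path / d), format="csv-long")
            h.append(_file_hash(path))
        assert h[0] == h[1]

    def test_manifest_hash_tracks_config(self, tiny_ensemble):
        sim = mini_sim_config()
        d1 = generate_smt(tiny_ensemble, 2, sim, master_seed=5)
        d2 = generate_smt(tiny_ensemble, 2, sim, master_seed=5)
        d3 = generate_smt(tiny_ensemble, 2,
                          mini_sim_config(injury_size=15), master_seed=5)
        assert d1.config_hash == d2.config_hash
        assert d1.config_hash != d3.config_hash

    def test_unknown_format_rejected(self, tmp_path, tiny_smt):
        with pytest.raises(ParameterError):
            export_smt(tiny_smt, str(tmp_path / "x"), format="parquet")
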