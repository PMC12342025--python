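"""Shared fixtures: catalogs, base MRM, and fast simulation configurations."""

import numpy as np
import pytest

from smtgen import (
    ReferenceConfig,
    SimulationConfig,
    build_base_mrm,
    default_entity_catalog,
    default_rule_catalog,
    generate_synthetic_reference,
)


@pytest.fixture(scope="session")
def entities():
    return default_entity_catalog()


@pytest.fixture(scope="session")
def rules():
    return default_rule_catalog()


@pytest.fixture(scope="session")
def base_mrm():
    return build_base_mrm()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mini_sim_config(**overrides) -> SimulationConfig:
    """Very small simulation for unit tests (3 full day-bins)."""
    defaults = dict(
        grid_width=10,
        grid_height=10,
        census={"macrophage": 6, "neutrophil": 6, "TH0": 4, "TH1": 2,
                "TH2": 2, "precursor": 4},
        injury_size=14,
        duration=29,
        sampling_interval=1,
        steps_per_day=10.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def mini_reference_config(**overrides) -> ReferenceConfig:
    defaults = dict(
        subjects_per_cohort={"A": 4, "B": 4},
        hidden_mrms_per_cohort=1,
        injury_range={"A": (8, 14), "B": (16, 26)},
    )
    defaults.update(overrides)
    return ReferenceConfig(**defaults)


@pytest.fixture(scope="session")
def mini_sim():
    return mini_sim_config()


@pytest.fixture(scope="session")
def mini_reference(base_mrm, mini_sim):
    """Small synthetic two-cohort reference plus its hidden truth."""
    cfg = mini_reference_config()
    dataset, truth = generate_synthetic_reference(cfg, mini_sim, base=base_mrm, seed=77)
    return cfg, dataset, truth
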