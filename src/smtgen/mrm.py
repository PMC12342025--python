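"""The Model Rule Matrix (MRM) and its genetic operators.

An MRM is a real matrix with one row per behavioral rule (25 by default) and
one column per mediator entity (17 by default). Element (r, j) is the signed
strength of entity j's contribution to the drive of rule r. Zeros denote
interactions absent from the explicitly coded base model — a latent space of
unrepresented connections that calibration may populate ("enrichment").
Coefficients are bounded in a closed interval, [-2, +2] by default, so the
maximal achievable per-element range across any ensemble is 4.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .catalogs import (
    DEFAULT_BASE_INTERACTIONS,
    EntityCatalog,
    RuleCatalog,
    RuleDescriptor,
    default_entity_catalog,
    default_rule_catalog,
)
from .errors import ConfigurationError, ParameterError, ParseError

DEFAULT_BOUNDS = (-2.0, 2.0)


@dataclass
class ModelRuleMatrix:
    """Rules-by-entities coefficient matrix with catalogs and bounds."""

    entities: EntityCatalog
    rules: RuleCatalog
    values: np.ndarray          # (n_rules, n_entities) float
    base_mask: np.ndarray       # (n_rules, n_entities) bool
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.base_mask = np.asarray(self.base_mask, dtype=bool)
        shape = (len(self.rules), len(self.entities))
        if self.values.shape != shape or self.base_mask.shape != shape:
            raise ConfigurationError(
                f"MRM shape {self.values.shape} does not match catalogs {shape}"
            )
        lo, hi = self.bounds
        if lo >= hi:
            raise ConfigurationError("lower bound must be below upper bound")
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ConfigurationError("MRM values outside coefficient bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.values))

    def copy_with(self, values: np.ndarray) -> "ModelRuleMatrix":
        return replace(self, values=np.array(values, dtype=float))

    def same_catalogs(self, other: "ModelRuleMatrix") -> bool:
        return (
            self.entities.names == other.entities.names
            and self.rules.names() == other.rules.names()
            and self.bounds == other.bounds
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelRuleMatrix):
            return NotImplemented
        return (
            self.same_catalogs(other)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.base_mask, other.base_mask)
        )


@dataclass(frozen=True)
class RangeMatrix:
    """Per-element value range (max - min) across an ensemble of MRMs."""

    ranges: np.ndarray

    def max_change(self, other: "RangeMatrix") -> float:
        return float(np.max(np.abs(self.ranges - other.ranges)))


def build_base_mrm(
    entities: EntityCatalog | None = None,
    rules: RuleCatalog | None = None,
    interactions: tuple[tuple[str, str, float], ...] = DEFAULT_BASE_INTERACTIONS,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> ModelRuleMatrix:
    """Construct the sparse base MRM holding only explicitly modeled interactions.

    Every element not named in ``interactions`` is zero and marked latent in
    ``base_mask`` — available for calibration to enrich.
    """
    entities = entities or default_entity_catalog()
    rules = rules or default_rule_catalog()
    shape = (len(rules), len(entities))
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for rule_name, entity_name, coeff in interactions:
        try:
            i = rules.index(rule_name)
            j = entities.index(entity_name)
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(
                f"base interaction ({rule_name}, {entity_name}) not in catalogs"
            ) from exc
        values[i, j] = coeff
        mask[i, j] = True
    mrm = ModelRuleMatrix(entities, rules, values, mask, bounds)
    if mrm.nonzero_count() / values.size >= 0.5:
        raise ConfigurationError("base MRM must be sparse (nonzero fraction < 0.5)")
    return mrm


def mutate(
    mrm: ModelRuleMatrix,
    rate: float,
    scale: float,
    rng: np.random.Generator,
) -> ModelRuleMatrix:
    """Perturb each element independently with probability ``rate``.

    Additive uniform noise on [-scale, +scale], then clipped to the coefficient
    bounds. Latent zeros may become nonzero: this is the enrichment mechanism
    by which calibration populates interactions absent from the base model.
    """
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(f"mutation rate must be in [0, 1], got {rate}")
    if scale <= 0:
        raise ParameterError(f"mutation scale must be positive, got {scale}")
    hit = rng.random(mrm.values.shape) < rate
    noise = rng.uniform(-scale, scale, size=mrm.values.shape)
    values = np.where(hit, mrm.values + noise, mrm.values)
    values = np.clip(values, *mrm.bounds)
    return mrm.copy_with(values)


def crossover(
    a: ModelRuleMatrix,
    b: ModelRuleMatrix,
    rng: np.random.Generator,
) -> ModelRuleMatrix:
    """Uniform elementwise recombination: each element drawn from a or b."""
    if not a.same_catalogs(b):
        raise ConfigurationError("crossover parents must share catalogs and bounds")
    take_a = rng.random(a.values.shape) < 0.5
    values = np.where(take_a, a.values, b.values)
    return a.copy_with(values)


def element_ranges(ensemble: list[ModelRuleMatrix]) -> RangeMatrix:
    """Per-element max - min across an ensemble (the Fig-4-style range matrix)."""
    if not ensemble:
        raise ParameterError("element_ranges requires a nonempty ensemble")
    first = ensemble[0]
    for m in ensemble[1:]:
        if not first.same_catalogs(m):
            raise ConfigurationError("ensemble members must share catalogs")
    stack = np.stack([m.values for m in ensemble])
    return RangeMatrix(ranges=stack.max(axis=0) - stack.min(axis=0))


# -- serialization -----------------------------------------------------------

def serialize_mrm(mrm: ModelRuleMatrix, precision: int = 12) -> str:
    """JSON text with catalogs embedded; lossless at the stated precision."""
    payload = {
        "entities": {
            "names": list(mrm.entities.names),
            "units": list(mrm.entities.units),
            "observed_subset": list(mrm.entities.observed_subset),
        },
        "rules": [
            {
                "name": r.name,
                "owner": r.owner,
                "family": r.family,
                "target": r.target,
                "response": r.response,
                "bias": r.bias,
                "rate": r.rate,
            }
            for r in mrm.rules.rules
        ],
        "bounds": list(mrm.bounds),
        "values": [[round(float(v), precision) for v in row] for row in mrm.values],
        "base_mask": mrm.base_mask.astype(int).tolist(),
    }
    return json.dumps(payload)


def deserialize_mrm(text: str) -> ModelRuleMatrix:
    try:
        payload = json.loads(text)
        entities = EntityCatalog(
            names=tuple(payload["entities"]["names"]),
            units=tuple(payload["entities"]["units"]),
            observed_subset=tuple(payload["entities"]["observed_subset"]),
        )
        rules = RuleCatalog(
            rules=tuple(RuleDescriptor(**r) for r in payload["rules"])
        )
        mrm = ModelRuleMatrix(
            entities=entities,
            rules=rules,
            values=np.array(payload["values"], dtype=float),
            base_mask=np.array(payload["base_mask"], dtype=bool),
            bounds=tuple(payload["bounds"]),
        )
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise ParseError(f"malformed MRM JSON: {exc}") from exc
    return mrm
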