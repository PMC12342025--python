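"""Entity and rule catalogs.

The simulation tracks 17 molecular mediator entities. Nine of them (TNFa, IL-1b,
IL-1ra, IL-6, IL-4, IL-8, IL-10, GCSF, IFNg) correspond to cytokines routinely
measured in multiplexed blood-serum panels and are the ones matched against
clinical-style reference data. The remaining eight are latent mediator slots:
additional signaling species (IL-12, IL-13, TGFb, PAF, soluble receptors), a
cytotoxic-effector compartment standing in for reactive oxygen species, and a
damage-associated molecular pattern (DAMP) signal released by injured
endothelium. The exact mediator roster of the original endothelial-interface
model is not public; this catalog is a reconstruction at the same
dimensionality with the measured nine pinned to their clinical names.

The behavioral repertoire is 25 rules spread over seven cell types
(endothelial, macrophage, neutrophil, TH0, TH1, TH2, precursor) and five rule
families: cytokine upregulation (secretion), cytokine downregulation
(clearance), cell activation, cellular differentiation, and lifespan/damage.
Each rule reads a signed drive from the local mediator milieu; the Model Rule
Matrix supplies the per-entity weights of that drive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

# Rule families
UPREGULATION = "cytokine-upregulation"
DOWNREGULATION = "cytokine-downregulation"
ACTIVATION = "cell-activation"
DIFFERENTIATION = "cellular-differentiation"
LIFESPAN = "lifespan/apoptosis"

RULE_FAMILIES = (UPREGULATION, DOWNREGULATION, ACTIVATION, DIFFERENTIATION, LIFESPAN)

# Cell types
ENDOTHELIAL = "endothelial"
MACROPHAGE = "macrophage"
NEUTROPHIL = "neutrophil"
TH0 = "TH0"
TH1 = "TH1"
TH2 = "TH2"
PRECURSOR = "precursor"

CELL_TYPES = (ENDOTHELIAL, MACROPHAGE, NEUTROPHIL, TH0, TH1, TH2, PRECURSOR)

# Response-function kinds
LOGISTIC = "logistic"      # g(d) = 1 / (1 + exp(-(d + bias)))
CLIPPED = "clipped-linear"  # g(d) = clip(d + bias, 0, 1)

#: The nine cytokines matched to clinical multiplexed measurements.
OBSERVED_CYTOKINES = (
    "TNFa", "IL-1b", "IL-1ra", "IL-6", "IL-4", "IL-8", "IL-10", "GCSF", "IFNg",
)

#: Latent mediator slots completing the 17-entity roster.
LATENT_MEDIATORS = (
    "IL-12", "IL-13", "TGFb", "PAF", "sTNFr", "sIL-1r", "cytotox", "DAMP",
)


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered roster of mediator entities (MRM columns)."""

    names: tuple[str, ...]
    units: tuple[str, ...]
    observed_subset: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("entity names must be unique")
        if len(self.units) != len(self.names):
            raise ConfigurationError("one unit label per entity required")
        if any(i < 0 or i >= len(self.names) for i in self.observed_subset):
            raise ConfigurationError("observed_subset indices out of range")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def observed_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.observed_subset)


@dataclass(frozen=True)
class RuleDescriptor:
    """One behavioral rule of the cell-level model (an MRM row).

    ``target`` names what the rule acts on: an entity (for secretion or
    clearance), a cell state, or a lineage for differentiation rules.
    ``bias`` is a constant drive offset (the rule's tonic level with all
    mediators at zero); ``rate`` scales the rule's per-step effect.
    """

    name: str
    owner: str
    family: str
    target: str
    response: str = CLIPPED
    bias: float = 0.0
    rate: float = 1.0

    def __post_init__(self):
        if self.owner not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type {self.owner!r}")
        if self.family not in RULE_FAMILIES:
            raise ConfigurationError(f"unknown rule family {self.family!r}")
        if self.response not in (LOGISTIC, CLIPPED):
            raise ConfigurationError(f"unknown response kind {self.response!r}")


@dataclass(frozen=True)
class RuleCatalog:
    """Ordered roster of behavioral rules (MRM rows)."""

    rules: tuple[RuleDescriptor, ...]

    def __post_init__(self):
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ConfigurationError("rule names must be unique")

    def __len__(self) -> int:
        return len(self.rules)

    def index(self, name: str) -> int:
        for i, r in enumerate(self.rules):
            if r.name == name:
                return i
        raise KeyError(name)

    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rules)

    def owned_by(self, cell_type: str) -> list[int]:
        return [i for i, r in enumerate(self.rules) if r.owner == cell_type]

    def families_present(self) -> set[str]:
        return {r.family for r in self.rules}


def default_entity_catalog() -> EntityCatalog:
    """The default 17-entity catalog; entities 0-8 are the measured cytokines."""
    names = OBSERVED_CYTOKINES + LATENT_MEDIATORS
    return EntityCatalog(
        names=names,
        units=tuple("au" for _ in names),  # arbitrary concentration units
        observed_subset=tuple(range(len(OBSERVED_CYTOKINES))),
    )


def default_rule_catalog() -> RuleCatalog:
    """The default 25-rule catalog.

    Endothelium takes damage from cytotoxic effectors, heals under
    anti-inflammatory tone, and releases DAMP / IL-8 / PAF in proportion to its
    damage. Macrophages activate on DAMP and pro-inflammatory cytokines,
    secrete the bulk of the cytokine panel, and clear DAMP. Neutrophils are
    recruited by IL-8/PAF and secrete the cytotoxic effector that closes the
    damage feedback loop. TH0 cells polarize to TH1/TH2; precursors replenish
    the myeloid pool under GCSF drive.
    """
    r = RuleDescriptor
    rules = (
        # endothelial
        r("endo-damage", ENDOTHELIAL, LIFESPAN, "damage", CLIPPED, bias=-0.05, rate=0.12),
        r("endo-heal", ENDOTHELIAL, LIFESPAN, "heal", LOGISTIC, bias=0.0, rate=0.03),
        r("endo-secrete-DAMP", ENDOTHELIAL, UPREGULATION, "DAMP", CLIPPED, bias=0.6, rate=0.8),
        r("endo-secrete-IL-8", ENDOTHELIAL, UPREGULATION, "IL-8", CLIPPED, bias=-0.05, rate=0.6),
        r("endo-secrete-PAF", ENDOTHELIAL, UPREGULATION, "PAF", CLIPPED, bias=-0.05, rate=0.4),
        # macrophage
        r("mac-activation", MACROPHAGE, ACTIVATION, "activation", LOGISTIC, bias=-2.0, rate=0.35),
        r("mac-secrete-TNFa", MACROPHAGE, UPREGULATION, "TNFa", CLIPPED, bias=-0.05, rate=0.8),
        r("mac-secrete-IL-1b", MACROPHAGE, UPREGULATION, "IL-1b", CLIPPED, bias=-0.05, rate=0.7),
        r("mac-secrete-IL-6", MACROPHAGE, UPREGULATION, "IL-6", CLIPPED, bias=-0.05, rate=0.7),
        r("mac-secrete-IL-10", MACROPHAGE, UPREGULATION, "IL-10", CLIPPED, bias=-0.05, rate=0.5),
        r("mac-secrete-GCSF", MACROPHAGE, UPREGULATION, "GCSF", CLIPPED, bias=-0.05, rate=0.5),
        r("mac-secrete-IL-1ra", MACROPHAGE, UPREGULATION, "IL-1ra", CLIPPED, bias=-0.05, rate=0.5),
        r("mac-clear-DAMP", MACROPHAGE, DOWNREGULATION, "DAMP", LOGISTIC, bias=-1.0, rate=0.25),
        # neutrophil
        r("neut-activation", NEUTROPHIL, ACTIVATION, "activation", LOGISTIC, bias=-2.0, rate=0.35),
        r("neut-secrete-cytotox", NEUTROPHIL, UPREGULATION, "cytotox", CLIPPED, bias=-0.05, rate=0.9),
        r("neut-apoptosis", NEUTROPHIL, LIFESPAN, "death", LOGISTIC, bias=-3.0, rate=0.15),
        # T-cell compartment
        r("th0-diff-TH1", TH0, DIFFERENTIATION, TH1, LOGISTIC, bias=-3.0, rate=0.1),
        r("th0-diff-TH2", TH0, DIFFERENTIATION, TH2, LOGISTIC, bias=-3.0, rate=0.1),
        r("th1-activation", TH1, ACTIVATION, "activation", LOGISTIC, bias=-2.0, rate=0.3),
        r("th1-secrete-IFNg", TH1, UPREGULATION, "IFNg", CLIPPED, bias=-0.05, rate=0.5),
        r("th2-activation", TH2, ACTIVATION, "activation", LOGISTIC, bias=-2.0, rate=0.3),
        r("th2-secrete-IL-4", TH2, UPREGULATION, "IL-4", CLIPPED, bias=-0.05, rate=0.4),
        r("th2-secrete-IL-13", TH2, UPREGULATION, "IL-13", CLIPPED, bias=-0.05, rate=0.4),
        # precursors
        r("prec-diff-neutrophil", PRECURSOR, DIFFERENTIATION, NEUTROPHIL, LOGISTIC, bias=-2.5, rate=0.15),
        r("prec-diff-macrophage", PRECURSOR, DIFFERENTIATION, MACROPHAGE, LOGISTIC, bias=-3.0, rate=0.08),
    )
    return RuleCatalog(rules=rules)


#: Explicitly modeled interactions: (rule name, entity name, signed coefficient).
#: These populate the base MRM; every other element is a latent zero.
DEFAULT_BASE_INTERACTIONS: tuple[tuple[str, str, float], ...] = (
    # endothelial damage from cytotoxic effectors, amplified by TNFa
    ("endo-damage", "cytotox", 1.0),
    ("endo-damage", "TNFa", 0.4),
    # healing promoted by anti-inflammatory tone, suppressed by inflammation
    ("endo-heal", "IL-10", 0.6),
    ("endo-heal", "TGFb", 0.4),
    ("endo-heal", "TNFa", -0.6),
    ("endo-heal", "IL-1b", -0.4),
    # damaged endothelium broadcasts alarm and recruits neutrophils
    ("endo-secrete-DAMP", "cytotox", 0.4),
    ("endo-secrete-IL-8", "TNFa", 0.5),
    ("endo-secrete-IL-8", "IL-1b", 0.5),
    ("endo-secrete-IL-8", "DAMP", 0.6),
    ("endo-secrete-PAF", "DAMP", 0.8),
    # macrophage activation
    ("mac-activation", "DAMP", 1.2),
    ("mac-activation", "TNFa", 0.6),
    ("mac-activation", "IFNg", 0.6),
    ("mac-activation", "IL-10", -1.2),
    ("mac-activation", "TGFb", -0.8),
    # macrophage secretion program
    ("mac-secrete-TNFa", "DAMP", 0.8),
    ("mac-secrete-TNFa", "IFNg", 0.5),
    ("mac-secrete-TNFa", "IL-10", -1.0),
    ("mac-secrete-TNFa", "sTNFr", -0.4),
    ("mac-secrete-IL-1b", "DAMP", 0.8),
    ("mac-secrete-IL-1b", "TNFa", 0.4),
    ("mac-secrete-IL-1b", "IL-10", -0.8),
    ("mac-secrete-IL-6", "TNFa", 0.6),
    ("mac-secrete-IL-6", "IL-1b", 0.6),
    ("mac-secrete-IL-6", "IL-10", -0.6),
    ("mac-secrete-IL-10", "IL-6", 0.5),
    ("mac-secrete-IL-10", "IL-4", 0.6),
    ("mac-secrete-GCSF", "TNFa", 0.5),
    ("mac-secrete-GCSF", "IL-1b", 0.4),
    ("mac-secrete-IL-1ra", "IL-1b", 0.6),
    ("mac-secrete-IL-1ra", "IL-10", 0.5),
    ("mac-clear-DAMP", "DAMP", 0.8),
    # neutrophil recruitment/effector arm
    ("neut-activation", "IL-8", 1.0),
    ("neut-activation", "PAF", 0.6),
    ("neut-activation", "TNFa", 0.5),
    ("neut-activation", "IL-10", -0.8),
    ("neut-secrete-cytotox", "DAMP", 0.5),
    ("neut-secrete-cytotox", "TNFa", 0.5),
    ("neut-secrete-cytotox", "IL-10", -0.6),
    ("neut-apoptosis", "IL-10", 0.6),
    ("neut-apoptosis", "TGFb", 0.4),
    # T-cell polarization and effector cytokines
    ("th0-diff-TH1", "IFNg", 0.8),
    ("th0-diff-TH1", "TNFa", 0.4),
    ("th0-diff-TH1", "IL-4", -0.8),
    ("th0-diff-TH2", "IL-4", 1.0),
    ("th0-diff-TH2", "IL-10", 0.5),
    ("th0-diff-TH2", "IFNg", -0.6),
    ("th1-activation", "IFNg", 0.6),
    ("th1-activation", "IL-6", 0.4),
    ("th1-activation", "IL-10", -0.6),
    ("th1-secrete-IFNg", "TNFa", 0.4),
    ("th1-secrete-IFNg", "IL-10", -0.8),
    ("th2-activation", "IL-4", 0.6),
    ("th2-activation", "IL-6", 0.4),
    ("th2-secrete-IL-4", "IL-4", 0.4),
    ("th2-secrete-IL-4", "IL-6", 0.3),
    ("th2-secrete-IL-4", "IFNg", -0.6),
    ("th2-secrete-IL-13", "IL-4", 0.6),
    # myeloid replenishment
    ("prec-diff-neutrophil", "GCSF", 1.0),
    ("prec-diff-neutrophil", "IL-8", 0.4),
    ("prec-diff-macrophage", "GCSF", 0.5),
    ("prec-diff-macrophage", "IL-6", 0.4),
)
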