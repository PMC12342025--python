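# Methods

## The agent-based inflammation model

The simulator abstracts the endothelial–blood interface as a toroidal grid
(default 30×30; the calibration experiments use 12×12) tiled by endothelial
cells, each with a damage level in [0, 1]. Mobile immune cells — macrophages,
neutrophils, TH0/TH1/TH2 lymphocytes and a precursor pool — occupy grid
sites, move by random walk with chemotaxis toward DAMP + IL-8 gradients, and
act through 25 behavioral rules spanning five families: cytokine secretion
(upregulation), mediator clearance (downregulation), activation,
differentiation, and lifespan/damage. Seventeen mediator fields diffuse
(explicit 4-neighbor kernel, coefficient ≤ 0.25 for stability) and decay
multiplicatively each step.

Every rule computes a local drive `d = Σ_j M[r,j]·c_j + b_r` from the
mediator concentrations `c` at the acting cell's site, where `M` is the
Model Rule Matrix and `b_r` a fixed tonic offset, then applies a bounded
response: logistic `1/(1+e^{-d})` for activation, differentiation and death
probabilities; clipped-linear `clip(d, 0, 1)` for secretion and clearance
rates. Secretion is additionally proportional to the cell's activation (or,
for endothelium, its damage), so an all-zero matrix with no injury produces
identically zero mediator output.

Injury seeds a random contiguous patch of damaged endothelium (randomized
breadth-first growth) that releases a damage-associated signal (DAMP). The
canonical base parameterization then closes a positive loop — DAMP activates
macrophages, which secrete TNFa/IL-1b/IL-6; IL-8 and PAF recruit neutrophils
whose cytotoxic effector damages more endothelium — checked by
IL-10/IL-1ra/TGFb suppression, macrophage DAMP clearance, neutrophil
apoptosis and baseline healing. Outcome classification uses endothelial
integrity ("health" = 1 − mean damage): death below 0.2 (run truncates),
resolved at or above 0.8 at the end, persistent inflammation between. Small
injuries resolve, large ones kill, and the transition region is stochastic —
the model's source of outcome heterogeneity at fixed parameterization.

Updates are synchronous and vectorized per cell type. All within-step
effects commute: secretion is additive, clearance multiplicative, and state
updates read only the pre-step field snapshot. Update-order bias is
therefore structurally absent, which we prefer over randomizing an order
that would then need auditing; determinism per seed is exact (verified to
the byte across processes). All randomness flows through one
`numpy.random.Generator` per run; replicate and component seeds derive from
a master seed via `SeedSequence` spawn keys.

### Catalogs

The 17-entity and 25-rule catalogs are reconstructions at the published
dimensionality: the nine clinically measured cytokines (TNFa, IL-1b, IL-1ra,
IL-6, IL-4, IL-8, IL-10, GCSF, IFNg) occupy the observed slots; eight latent
slots hold additional signaling species (IL-12, IL-13, TGFb, PAF, soluble
receptors), the cytotoxic effector and the DAMP signal. Two latent entities
(sTNFr, sIL-1r) have no source in the base model; their columns are purely
latent structure available to enrichment. Rule-to-rule coefficient choices
are documented in `smtgen/catalogs.py`; they were set to produce the
qualitative regimes above (monotone injury–severity dose response, all three
outcomes reachable) and are not fitted to any dataset.

## Time, units and the reference generator

Time is abstract steps; `steps_per_day` (default 20 at full scale, 10 in the
calibration configuration) maps steps to clinical days. Durations are chosen
so every day-bin spans a full complement of steps (199 steps = 10 days at 20
steps/day; 89 steps = 9 days at 10 steps/day); a duration ending exactly on
a bin boundary would leave a degenerate one-sample bin that behaves
pathologically under min/max banding. Concentrations are arbitrary units.

The synthetic reference generator emulates the structure of multiplexed
cytokine studies: two outcome cohorts (A: injuries 10–22 grid sites on the
12×12 grid; B: 24–40), one hidden ground-truth MRM per cohort (base plus
uniform offsets up to ±0.8 at six randomly declared elements), 20 subjects
per cohort, each simulated with a subject-specific injury size and seed,
sampled at 3–8 irregular times, with multiplicative lognormal noise
(σ = 0.5, giving roughly an order-of-magnitude spread between extreme
measurements — the scale on which immunoassay panels actually vary).
Generated cohorts satisfy the overlap property — per mediator, the
between-cohort mean gap is smaller than the within-cohort range — which is
the regime that motivates envelope-based, distribution-free falsification.

One hidden MRM per cohort is deliberate: within-cohort heterogeneity comes
from insult size and intrinsic stochasticity. With two or more
per cohort, sparse sampling lets a time bin contain observations from only
one of them, and the other is then genuinely (but spuriously, for a recovery
experiment) falsified by its own cohort.

What the generator does *not* emulate: assay detection limits and
left-censoring, batch effects, missing-at-random panels, patient dropout,
and treatment effects. Passing recovery tests on this generator demonstrates
that the pipeline can invert its own forward model under sparsity and noise
— not that it recovers mechanisms from real cohorts.

## Falsification

An MRM is tested against a cohort's envelope by running replicate
simulations whose injury sizes sweep the cohort's insult range (replicate
count ≥ 2; the boundary-mapping loop uses 3, final verdicts on ensembles and
hidden truths use 6, because the replicate band is a finite-sample estimate
of the model's trajectory space and too few replicates produce knife-edge
false rejections). For each constrained (entity, day-bin): the simulated
band is the min/max of the grid-mean aggregate over all replicate samples in
the bin; the bin is covered iff the band intersects the envelope interval;
the verdict is non-falsified iff every bin is covered. Intersection is the
weakest criterion that still rejects — appropriate when the goal is an
expansive ensemble — and strict band-containment is available as a switch.

The envelope expansion factor α defaults to 1.5. With multiplicative noise,
a bin's observed min/max can land entirely below (or above) the generating
model's own attainable band, so at α = 1 even ground-truth parameterizations
are rejected with non-trivial probability; α = 1.5 absorbs those tail events
while aggressive random perturbations of the base matrix are still rejected
at high rate. This is the operational form of treating outliers as points
within a larger potential distribution rather than as bounds.

## Calibration: GA enrichment + AL boundary mapping

The genetic algorithm evolves a population (default 24) consisting of the
incumbent base matrix plus mutants of it: uniform additive mutation (rate
0.05, base scale 0.5, clipped to bounds — latent zeros may become nonzero,
which is the enrichment move), uniform elementwise crossover, binary
tournament selection, elitism (best fitness is non-decreasing), fitness =
mean coverage fraction over the evaluated cohorts with ties broken toward
fewer violations then smaller deviation from base. Two additions make the
search robust when the data-generating dynamics are far from base. First,
offspring mutation scales are heavy-tailed (1x/2x/4x the base scale), so
occasional large moves can escape coverage plateaus. Second, half the
offspring receive a *violation-guided repair*: a violated bin names the
entity whose simulated band lies above or below the envelope, and because
mediator concentrations are nonnegative, shifting the coefficients of that
entity's secretion rule moves its output monotonically — the repair damps
the whole rule row when the entity is overproduced, and pulls the row back
toward the base row (or bumps a coefficient) when it is underproduced,
which also escapes the dead zone where a saturated clipped response yields
no incremental signal. The search stops early once full coverage is reached
*and* at least half a population's worth of non-falsified candidates exist
to seed boundary mapping; the pipeline retries a failed cohort with up to
two fresh-seeded restarts before declaring calibration failure.

The active-learning loop then maps the non-falsifiable region per cohort.
Each round fits a random-forest classifier on flattened MRM vectors labeled
by verdict, proposes a pool of candidates, simulates the batch with the most
uncertain predictions (|p − 0.5| minimal), and adds the labels; it stops
after the configured rounds or when the ensemble range matrix changes less
than a tolerance. The proposal distribution is shaped by two empirical
facts: diffuse large perturbations are almost always falsified (the valid
region is thin in most joint directions), and symmetric offsets waste half
their probes inside the already-mapped range. Proposals therefore touch few
elements at a time (2% of the matrix, ~8 elements), selected stratified by
per-element probe count so coverage of all 425 elements is even, and jump
*outward* past the ensemble's current per-element extremes by uniform steps
(scale 1.0, clipped to bounds). Half the proposals are parented on the
least-deviant valid members, so per-element tolerances are not confounded by
drift elsewhere in the matrix. Candidates are evaluated per cohort; an MRM
non-falsified against cohort B's envelope is a B-type member, mirroring
separately parameterized trajectory spaces per outcome group.

The returned valid ensemble is every non-falsified candidate observed, with
provenance; its range matrix (per-element max − min) is the boundary
characterization. Ensembles are archived as member JSON files plus manifest.

## Recovery, expansiveness and separation diagnostics

`recover_parameters_check` reports, per hidden MRM, the fraction of matrix
elements (and of the declared-perturbed subset) whose hidden value lies
within the ensemble's per-element [min, max], plus a re-falsification
verdict at 6 replicates. `expansion_check` reports, per measured cytokine,
how far the synthetic trajectory envelope extends beyond the observed
reference extremes. `compute_separation` reports, per entity, the time
intervals where the two cohorts' envelopes are disjoint and the overlap
fraction; the experiment additionally counts disjoint regions whose
containing day-bin shows no separation in the sparse reference bins —
discriminative windows that only the dense synthetic data reveals.

## Problem sizes

The shipped experiments run on one CPU: the recovery study uses the 12×12
grid, 89-step runs, 2 × 20 subjects, GA population 24 (≤ 30 generations,
replicates 3), AL 5 rounds × 200 evaluations per cohort (~7 minutes); the
enrichment statistic re-runs the GA 10 times (~40 s); heterogeneity,
self-consistency, expansion/separation and determinism each take seconds.
The 30×30 default configuration is for trajectory-space exploration, not for
the calibration loop.

## Known limitations

- The rule set is a structural reconstruction, not a validated immunology
  model; coefficients shape qualitative regimes only.
- Per-element ranges from the boundary walk are lower bounds on the true
  non-falsifiable ranges; correlated directions (coefficient combinations
  valid only jointly) are explored only through GA recombination and
  multi-element probes.
- Falsification verdicts are stochastic at fixed settings; replicate counts
  trade verdict stability against compute.
- Grid-mean aggregates discard spatial structure; an envelope over local
  concentrations would falsify differently.
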