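# smtgen

Synthetic mediator trajectory (SMT) generation from ensemble-calibrated
agent-based models of systemic inflammation.

## The problem

Multiplexed cytokine panels — IL-1b, IL-1ra, IL-6, IL-4, IL-8, IL-10, GCSF,
IFNg, TNFa measured serially in blood — are the raw material for forecasting
sepsis and ARDS trajectories and for evaluating immunomodulatory therapies.
But this data is structurally hostile to statistical synthetic-data methods:
each added mediator inflates the configuration space exponentially (the data
is *perpetually sparse* relative to it), the measurements are neither
independent nor randomly sampled (so no normality assumption survives), and
clinical logistics cap sampling at a handful of irregular time points per
patient. Within-cohort spread routinely exceeds between-cohort mean
differences, so fitting means discards exactly the heterogeneity a
forecasting model must learn.

`smtgen` implements the alternative: a mechanism-based route to synthetic
data. A stochastic cell-level model of the endothelial–blood interface
generates dense mediator trajectories; its behavioral rules read their
coefficients from a **Model Rule Matrix (MRM)**; and a calibration pipeline
retains *every* parameterization that sparse clinical-style observations
cannot reject, rather than a single best fit. Trajectories generated from
that non-falsified ensemble are maximally expansive — they cover, and
deliberately extend beyond, the observed data — which is what a training set
for a generalizable forecasting model needs.

## The core objects

- **Model Rule Matrix** `M ∈ [-2, 2]^(25×17)`: rows are behavioral rules
  (secretion, clearance, activation, differentiation, lifespan/damage across
  endothelial cells, macrophages, neutrophils, TH0/TH1/TH2 lymphocytes and
  precursors), columns are 17 mediator entities. Element `M[r, j]` is the
  signed weight of mediator `j` in rule `r`'s local drive
  `d = Σ_j M[r, j]·c_j + b_r`, passed through a bounded response (logistic or
  clipped-linear). Zeros are *latent interactions*: absent from the base
  model, available to calibration. The maximal per-element ensemble range is
  therefore 4.0.
- **Falsification envelope**: per (cohort, entity, day-bin) min/max bands of
  the observations, widened by a factor α ≥ 1 because observed extremes are
  samples from a larger attainable range, never true bounds. A
  parameterization is *non-falsified* when the min/max band of its stochastic
  replicates intersects every constrained bin.
- **Valid ensemble / range matrix**: all non-falsified MRMs found by a
  genetic algorithm (which enriches latent elements) plus an active-learning
  loop (which probes the boundary of the non-falsifiable region with a
  surrogate classifier); the ensemble's per-element value ranges characterize
  that boundary.
- **SMT dataset**: dense labeled trajectories from every ensemble member with
  stochastic replicates, plus per-cohort envelopes, a separation profile
  (times where cohort trajectory spaces are disjoint) and an expansion
  summary (how far the synthetic envelope exceeds observed extremes).

## Worked example

```python
import numpy as np
from smtgen import (build_base_mrm, toy_simulation_config, ReferenceConfig,
                    generate_synthetic_reference, build_envelope,
                    GAConfig, ALConfig, calibrate)

base = build_base_mrm()
sim = toy_simulation_config()            # 12x12 grid, ~9 simulated days
ref_cfg = ReferenceConfig()              # 2 cohorts x 20 subjects

dataset, truth = generate_synthetic_reference(ref_cfg, sim, base=base, seed=11)
print(len(dataset), dataset.overlap_property_holds())
# 1980 True        <- 1980 sparse noisy observations; within-cohort range
#                     exceeds the between-cohort mean gap for all 9 cytokines

envelope = build_envelope(dataset, bin_width=1.0, alpha=1.5)
ensemble = calibrate(base, envelope,
                     GAConfig(population_size=12, generations=10, seed=3),
                     ALConfig(batch_size=30, pool_size=60, rounds=3, seed=4),
                     sim, injury_ranges=ref_cfg.injury_range)
nz = [m.nonzero_count() for m in ensemble.mrms()]
print(len(ensemble), base.nonzero_count(), int(np.median(nz)))
# 125 63 81        <- 125 non-falsified MRMs; the evolved matrices carry a
#                     median 81 nonzero interactions vs 63 in the sparse
#                     base: calibration populated latent elements
```

The `examples/` directory walks each capability end to end with printed,
annotated output: `01` MRM and genetic operators, `02` stochastic trajectory
spaces and the injury dose–response, `03` synthetic sparse reference data and
envelopes, `04` full GA + AL calibration with hidden-parameter recovery,
`05` SMT generation with separation and expansion diagnostics.

A thin CLI wraps the same pipeline for shell use:

```bash
smtgen make-reference run.yaml        # reference CSV + envelope + hidden truth
smtgen calibrate run.yaml out/reference.csv
smtgen generate run.yaml out/ensemble --reference out/reference.csv
smtgen check run.yaml out/reference.csv out/ensemble
```

## Scope

The simulator is a reduced-fidelity reconstruction at the published
dimensionality (17 entities, 25 rules, the named cell types), built for
calibration-scale experiments on a desktop — not a port of any specific
published model's rule equations. Training neural networks on the generated
SMTs is deliberately out of scope. See `docs/methods.md` for the model,
parameter and design details.
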