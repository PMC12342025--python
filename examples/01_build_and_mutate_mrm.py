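"""Build the base Model Rule Matrix and apply the genetic operators.

The MRM is the package's central object: 25 behavioral rules (rows) by 17
mediator entities (columns), with signed coefficients in [-2, 2]. The base
matrix holds only the explicitly modeled interactions; everything else is a
latent zero that calibration may enrich.
"""

import numpy as np

from smtgen import build_base_mrm, crossover, element_ranges, mutate

base = build_base_mrm()
print(f"base MRM: {base.shape[0]} rules x {base.shape[1]} entities")
print(f"nonzero interactions: {base.nonzero_count()} "
      f"({base.nonzero_count() / base.values.size:.1%} dense)")
print(f"coefficient bounds: {base.bounds} -> maximal element range "
      f"{base.bounds[1] - base.bounds[0]}")

rng = np.random.default_rng(7)
child_a = mutate(base, rate=0.05, scale=0.5, rng=rng)
child_b = mutate(base, rate=0.05, scale=0.5, rng=rng)
cross = crossover(child_a, child_b, rng)
print(f"mutant nonzeros: {child_a.nonzero_count()} "
      f"(+{child_a.nonzero_count() - base.nonzero_count()} enriched latent elements)")

ranges = element_ranges([base, child_a, child_b, cross])
print(f"ensemble of 4 -> per-element range matrix, max spread "
      f"{ranges.ranges.max():.3f} at "
      f"{np.unravel_index(ranges.ranges.argmax(), ranges.ranges.shape)}")
# The spread map is the object that later characterizes how far each
# coefficient can move before sparse clinical-style data rejects it.
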