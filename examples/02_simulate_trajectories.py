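"""Run the inflammation simulator and look at stochastic trajectory spaces.

One parameterization plus one injury size still produces a *distribution* of
outcomes, because cell placement, movement and differentiation are
stochastic. Replicates sweep out a min/max envelope: the trajectory space.
"""

import numpy as np

from smtgen import build_base_mrm, run_replicates, run_simulation, toy_simulation_config

base = build_base_mrm()
cfg = toy_simulation_config()  # 12x12 endothelial grid, ~9 simulated days

traj = run_simulation(cfg, base, seed=1)
tnf = traj.values[:, base.entities.index("TNFa")]
print(f"single run: outcome={traj.outcome}, terminal health "
      f"{traj.terminal_health:.2f}, peak TNFa {tnf.max():.2f} au "
      f"at day {traj.times[tnf.argmax()] / cfg.steps_per_day:.1f}")

for injury in (0, 10, 20, 120):
    t = run_simulation(toy_simulation_config(injury_size=injury), base, seed=1)
    print(f"injury {injury:3d} sites -> outcome {t.outcome:24s} "
          f"terminal health {t.terminal_health:.2f}")

space = run_replicates(cfg, base, n=12, base_seed=3)
term = [r.terminal_health for r in space.replicates]
print(f"12 replicates, same parameterization: terminal health "
      f"{min(term):.3f}..{max(term):.3f} (variance {np.var(term):.5f})")
width = (space.envelope_max - space.envelope_min).mean(axis=0)
j = int(np.argmax(width))
print(f"widest envelope band: {base.entities.names[j]} "
      f"(mean width {width[j]:.3f} au) — stochasticity alone already "
      f"spreads the trajectory space")
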