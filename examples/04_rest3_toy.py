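"""Solute tempering on a toy system: ladder tuning and acceptance.

Builds a 1-D system with a steep linear solute-environment coupling
(so neighbouring replicas sample well-separated coupling energies),
finds the smallest geometric replica ladder whose worst neighbour-pair
exchange acceptance clears the 20% floor of the 20-30% working band on
short pilot runs, then runs the tuned ladder and prints per-pair
acceptance.  The campaign accounting at the end mirrors a 23-window
study: 20 tempered windows totalling 176 replicas plus 3 plain
bulk-water windows at 250 ns each.
"""

import numpy as np

from permeapath.rest3 import ToyTemperedSystem, plan_campaign, run_toy_rest3, tune_ladder
from permeapath.synthetic import LangevinConfig

system = ToyTemperedSystem(
    u_env=lambda z: np.zeros_like(np.asarray(z, float)),
    u_int=lambda z: 60.0 * np.asarray(z, float),
    z_min=0.0, z_max=2.0, diffusivity=1e-3)

cfg = LangevinConfig(dt=0.01, n_steps=60_000, sample_stride=20,
                     equilibration_steps=10_000, seed=4)
tuning = tune_ladder(system, center=1.0, spring_k=0.0, cfg=cfg, lambda_min=0.05)
print(f"tuned ladder ({tuning.status}): "
      + ", ".join(f"{l:.3f}" for l in tuning.ladder.lambdas))

window, stats = run_toy_rest3(system, tuning.ladder, 1.0, 0.0,
                              LangevinConfig(dt=0.01, n_steps=200_000,
                                             sample_stride=10,
                                             equilibration_steps=20_000, seed=5))
for i, frac in enumerate(stats.acceptance_fractions):
    print(f"pair {i}<->{i+1}: acceptance {frac:.2f} "
          f"({stats.accepts[i]}/{stats.attempts[i]})")

centers = np.round(np.arange(0.0, 4.41, 0.2), 9)
schemes = {c: (9 if k < 16 else 8) for k, c in enumerate(centers[centers <= 3.81])}
plan = plan_campaign(centers.tolist(), schemes, 250.0)
print(f"campaign: {plan.n_replicas} replicas, {plan.total_time_ns:,.0f} ns total")
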