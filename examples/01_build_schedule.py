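"""Build the dual dynamic schedule and inspect its stage structure.

Stage durations grow geometrically (lambda = 1/gamma), the noise multiplier
grows by 1/beta per stage, and the clipping threshold decays by a per stage;
the effective injected noise power (sigma_i * C_i)^2 therefore *shrinks*
whenever a < beta.
"""

from sdd_dpsgd import (
    ScheduleConfig,
    build_table,
    expenditure_profile,
    noise_variance_trajectory,
    schedule_stats,
)

config = ScheduleConfig(
    total_iterations=2000,  # optimizer iterations, not epochs
    sigma0=1.0,             # initial noise multiplier
    c0=5.0,                 # initial (high) clipping threshold
    gamma=0.9,              # step increment; lambda = 1/0.9
    beta=0.8,               # conservative noise step ratio (growth 1.25/stage)
    clip_decay=0.6,         # threshold decay per stage
    rho=0.3,                # stage 0 must cover >= 30% of training
    n=3,
)

table = build_table(config)
stats = schedule_stats(table)

print("stage durations:", table.durations, "(sum =", table.total_iterations, ")")
print("noise multipliers:", [round(s, 4) for s in table.sigmas])
print("clip thresholds:  ", [round(c, 4) for c in table.clips])
print("noise power V_i:  ", [round(v, 3) for v in noise_variance_trajectory(table)])
print("RDP cost proxy D_i/sigma_i^2:",
      [round(x, 1) for x in expenditure_profile(table)])
print(f"stage-0 fraction D0/T = {stats.d0_fraction:.3f} (protection rho = 0.3)")
print(f"duration-weighted sigma: mean {stats.weighted_mean:.4f}, "
      f"variance {stats.weighted_variance:.4f}")
# The first stage holds ~30% of training at the lowest noise and the highest
# threshold — that is the window in which fragile minority-class gradients
# survive clipping and noise.
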