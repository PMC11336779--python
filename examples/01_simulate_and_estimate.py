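"""Simulate a pocket-IMU walk and recover gait parameters end to end.

Generates a 30 s steady walk (step length 0.60 m, leg length 0.90 m, cadence
1.8 steps/s) with realistic sensor noise, runs the full pipeline (orientation
→ vertical acceleration → heel strikes → double integration → pendulum step
length), and compares the per-stride estimates with the generator's truth.
"""

import numpy as np

import pocketgait as pg

profile = pg.WalkProfile.constant(
    step_length=0.6, cadence=1.8, duration_s=30.0, leg_length=0.9,
    noise_sd=0.5, seed=42,
)
rec, truth = pg.simulate_imu_walk(profile)
table = pg.estimate_gait(rec)

sl = np.concatenate([table.step_length_1_m, table.step_length_2_m])
print(f"strides retained:      {len(table)}")
print(f"stride time  mean±SD:  {table.stride_time_s.mean():.3f} ± {table.stride_time_s.std():.3f} s   (truth {2/1.8:.3f} s)")
print(f"step length  mean±SD:  {sl.mean():.3f} ± {sl.std():.3f} m   (truth 0.600 m)")
print(f"gait speed   mean±SD:  {table.speed_mps.mean():.3f} ± {table.speed_mps.std():.3f} m/s (truth {1.2/(2/1.8):.3f} m/s)")
print()
print("Stride times come from heel-strike peak timing and are nearly exact;")
print("step lengths inherit the noise of the doubly-integrated vertical")
print("position, so their scatter is larger — this is the error the zone")
print("coefficients are designed to correct on real data.")
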