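"""Method-agreement statistics for validating a wearable against a reference.

Simulates per-stride gait speeds from an app and a reference device, then
computes Passing–Bablok regression (systematic proportional/constant bias),
Bland–Altman limits of agreement (magnitude of disagreement), and ICC(1,1)
test–retest reliability across repeated trials.
"""

import numpy as np

import pocketgait as pg

rng = np.random.default_rng(7)

# paired per-stride gait speeds: app reads 5% high; both devices are noisy
# (Passing-Bablok assumes measurement error in both variables)
speed = rng.uniform(0.8, 1.4, 200)
ref = speed + rng.normal(0, 0.05, 200)
app = 1.05 * speed + rng.normal(0, 0.05, 200)

pb = pg.passing_bablok(ref, app)
print(f"Passing-Bablok: slope {pb.slope:.3f} (95% CI {pb.slope_ci[0]:.3f}-{pb.slope_ci[1]:.3f}), "
      f"intercept {pb.intercept:.3f} m/s")
ba = pg.bland_altman(ref, app)
print(f"Bland-Altman:   bias {ba.bias:+.3f} m/s, LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] m/s")

# test-retest: 10 subjects x 3 trials of per-trial mean gait speed
subject_speed = rng.uniform(0.9, 1.3, 10)
trials = subject_speed[:, None] + rng.normal(0, 0.05, (10, 3))
icc = pg.icc_1_1(trials)
print(f"ICC(1,1):       {icc.icc:.2f} (95% CI {icc.ci[0]:.2f}-{icc.ci[1]:.2f}) -> {icc.label}")
print()
print("A slope near 1 with intercept near 0 means no systematic bias; the LoA")
print("span is the expected per-stride disagreement; ICC > 0.75 is excellent")
print("test-retest reliability, 0.6-0.75 good.")
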