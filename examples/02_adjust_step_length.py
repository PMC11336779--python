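"""Apply the built-in zone-coefficient correction to raw step lengths.

The raw pendulum estimate under-shoots short steps and over-shoots long ones;
each estimate is multiplied by the coefficient of the step-length zone it
falls in (zones 0.2–0.5 / 0.5–0.8 / 0.8–1.1 m).
"""

import pocketgait as pg

coeffs = pg.default_coefficients("all")
print("zone edges   :", coeffs.zone_edges)
print("coefficients :", coeffs.coefficients)
print()
for raw in (0.30, 0.50, 0.60, 0.80, 0.90):
    adjusted, zone, _ = pg.apply_adjustment(raw, coeffs)
    print(f"raw {raw:.2f} m -> zone {coeffs.zone_label(zone)} m "
          f"x {coeffs.coefficients[zone]:.2f} -> adjusted {adjusted:.3f} m")
print()
print("Short raw estimates are inflated (coefficient > 1), long ones shrunk")
print("(coefficient < 1); mid-range steps are nearly unchanged. Adjusted gait")
print("speed is always recomputed from the adjusted step lengths.")
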