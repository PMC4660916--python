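"""Barriers and Néel times of one particle under an oblique reduced field.

A 14 nm magnetite particle (K_eff = 1.6e4 J/m^3, T = 293 K) sits in a
field tilted 30 degrees from its easy axis.  As the reduced field h grows
toward the critical value h_c(psi), the escape barriers collapse and both
Néel-time models accelerate; the analytic model carries the
curvature-corrected attempt rate, the discrete-orientation model the bare
Arrhenius one.
"""

import math

from slpsim import (
    MaterialParams,
    coffey_barriers,
    critical_field,
    neel_time_coffey,
    neel_time_discrete,
    pfeiffer_barriers,
)

material = MaterialParams(K_eff=1.6e4)
KB, T = 1.380649e-23, 293.0
sigma = material.K_eff * (math.pi / 6) * (14e-9) ** 3 / (KB * T)
psi = math.radians(30.0)
hc = critical_field(psi)
print(f"sigma = {sigma:.3f}, psi = 30 deg, h_c = {hc:.4f}")
print(f"{'h':>6} {'beta_low(exact)':>16} {'beta_low(Pfeiffer)':>19} "
      f"{'tau_coffey (s)':>15} {'tau_discrete (s)':>17}")
for frac in (0.0, 0.2, 0.4, 0.6, 0.8):
    h = frac * hc
    bc = coffey_barriers(psi, h, sigma)
    bp = pfeiffer_barriers(psi, h, sigma)
    tc = neel_time_coffey(psi, h, sigma, material)
    td = neel_time_discrete(bp, material.tau0)
    print(f"{h:6.3f} {bc.lower:16.4f} {bp.lower:19.4f} {tc:15.3e} {td:17.3e}")
print("\nBarriers fall from sigma at h = 0 to zero at h_c; the Pfeiffer")
print("interpolation tracks the exact lower barrier to a few percent.")
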