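"""Full chain on one interacting ensemble.

Builds 300 magnetite particles (10 nm) at 10 % volume fraction on the
lattice, assigns random easy axes, computes Ewald dipolar local fields
under a 15 kA/m, 300 kHz protocol, and reports relaxation times and SLP
for both Néel-time models.
"""

import numpy as np

from slpsim import Environment, FieldProtocol, MaterialParams, simulate_system

material, env, protocol = MaterialParams(), Environment(), FieldProtocol()
res = simulate_system(300, 0.10, 10e-9, material, env, protocol, "random", seed=1)

st = res["states"]
print(f"external field: {protocol.H0 / 1e3:.0f} kA/m at {protocol.f / 1e3:.0f} kHz")
print(f"local |H|: mean {st.H.mean() / 1e3:.2f} kA/m, "
      f"spread {st.H.std() / 1e3:.2f} kA/m (dipolar broadening)")
print(f"reduced field h: mean {st.h.mean():.3f}; sigma = {st.sigma[0]:.2f}")
for model in ("discrete", "coffey"):
    s = res[model]["summary"]
    r = res[model]["slp"]
    print(f"{model:9s} mean tau_N = {s.mean_tau_N:.3e} s, "
          f"tau_B = {s.tau_B:.3e} s, mean tau_eff = {s.mean_tau_eff:.3e} s, "
          f"SLP = {r.slp / 1e3:.1f} W/g ({s.n_excluded} particles past h_c excluded)")
print("\nThe dipolar fields tilt and broaden the local-field distribution;")
print("particles pushed past the critical field lose their barrier and are")
print("excluded from the ensemble averages.")
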