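"""SLP of two experimental iron-oxide samples.

Evaluates both Néel-time models on the printed sample parameters
(core/hydrodynamic diameters, volume fraction, anisotropy, 24.5 kA/m at
400 kHz, measured chi_0) with 1000-particle ensembles, random axes and
three seeds, and prints the SLP per gram of magnetic material.
"""

from slpsim import TABLE1, reproduce_table2

df = reproduce_table2(seeds=(1, 2, 3), n=1000)
for _, r in df.iterrows():
    print(
        f"sample {int(r['row'])}: d = {r['d_m'] * 1e9:.1f} nm, "
        f"r_V = {r['r_V']:.4f}, chi0 = {r['chi0']}"
    )
    print(
        f"  discrete-orientation SLP = {r['slp_discrete_W_per_kg'] / 1e3:8.1f} W/g"
        f"  (seed spread {r['slp_discrete_std'] / 1e3:.1f})"
    )
    print(
        f"  adapted analytic SLP     = {r['slp_coffey_W_per_kg'] / 1e3:8.1f} W/g"
        f"  (seed spread {r['slp_coffey_std'] / 1e3:.1f})"
    )
    print(f"  particles past h_c excluded per run: {r['n_excluded_coffey']:.0f}/1000")
print("\nAt 24.5 kA/m these samples sit at the edge of the bistable regime:")
print("a large share of particles exceeds the critical reduced field and")
print("is excluded from the ensemble averages.")
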