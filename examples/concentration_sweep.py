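"""Relaxation and SLP versus nanoparticle concentration.

Sweeps the volume fraction of a 7 nm system over three values with two
seeds each and prints the seed-averaged Néel time and SLP per model.
Denser systems see stronger dipolar fields, hence lower barriers.
"""

from slpsim import SweepSpec, run_sweep

spec = SweepSpec(
    variable="r_V", grid=[0.02, 0.10, 0.20], repeats=2, n=200, d=7e-9,
    axes_modes=("random",), master_seed=1,
)
df = run_sweep(spec)
avg = (
    df.groupby(["value", "model"])[["mean_tau_N_s", "slp_W_per_kg"]]
    .mean()
    .reset_index()
)
print(f"{'r_V':>5} {'model':>9} {'mean tau_N (s)':>15} {'SLP (W/g)':>10}")
for _, r in avg.iterrows():
    print(f"{r['value']:5.2f} {r['model']:>9} {r['mean_tau_N_s']:15.3e} "
          f"{r['slp_W_per_kg'] / 1e3:10.1f}")
print("\nFor 7 nm particles the system responds on the rising flank of the")
print("Debye dispersion, so shorter relaxation times mean lower loss power.")
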