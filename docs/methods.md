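# Methods

## Scope and model chain

`slpsim` estimates the specific loss power (SLP) of suspensions of
interacting single-domain magnetite nanoparticles in the linear-response
regime. One evaluation runs:

1. **Ensemble construction** — monodisperse spheres on randomly chosen
   lattice sites in a periodic cubic box;
2. **Local fields** — external field amplitude plus the Ewald-summed
   dipole–dipole field of all neighbours and images;
3. **Energy landscape** — per-particle stationary points and barriers of
   the uniaxial free energy under the oblique local field;
4. **Relaxation** — Néel times from two models, the shared Brownian
   time, and the harmonic effective time;
5. **Loss power** — Debye out-of-phase response of the ensemble-averaged
   effective time, normalized per unit mass of magnetic material.

Everything is SI internally; loss powers are usually quoted in W/g.

## Ensemble generator

The generator emulates a colloid snapshot: `n` particles of core
diameter `d` occupy randomly selected sites (without replacement) of a
cubic lattice. The default site set is the vertices plus the three face
centres owned by each conventional cell (4 sites/cell, fcc-type,
nearest-neighbour spacing a/√2); a strict body-centred set
(`site_set="bcc"`) is available. The box edge L = (nV/r_V)^{1/3} makes
the achieved volume fraction exact for monodisperse spheres, and the
cell count per edge is the smallest that offers ≥ n sites, maximizing
the minimum separation. A requested fraction that would force
neighbours closer than one diameter raises an error naming the maximum
achievable fraction (≈ 0.185 n/m³ for the default site set with m cells
per edge).

Clusters are the same construction on a compact block sized by the
*local* fraction r_V,loc, centred in an otherwise empty periodic box
whose edge is set by the global fraction (default 0.1).

Easy axes are drawn i.i.d. uniformly on the sphere (`random`) or set to
the field direction (`parallel`). Moments start in the easy-axis
minimum nearest the field (`axis_aligned`; sign chosen for non-negative
projection on the field) — the configuration consistent with a system
near equilibrium, which is what linear response assumes. One master
seed feeds independent derived streams for placement and axis
assignment, so each stage is separately reproducible.

What the generator does **not** emulate: polydispersity of size or
anisotropy, coating layers (the hydrodynamic diameter is an input),
particle diffusion/aggregation dynamics, and thermal disorder of the
moment directions when the dipolar field is evaluated. Passing tests
therefore validate the model chain on idealized lattice colloids, not
the microstructure of a real ferrofluid.

## Dipolar fields

The dipolar field is kept in A/m (no μ₀ folded in) so it adds directly
to H_ext; the reduced field multiplies by μ₀ exactly once. For periodic
ensembles the conditionally convergent lattice sum is evaluated by Ewald
summation with conducting ("tinfoil") boundary conditions — the standard
convention that removes macroscopic shape dependence. Parameters are
auto-tuned from the box: real-space cutoff L/2, splitting parameter
α = erfc⁻¹(ε)/(L/2) and reciprocal cutoff k_max from
exp(−(πk/αL)²) ≈ ε, with default target ε = 1e-6 (measured end-to-end
accuracy ~1e-4 relative; tests use ε = 1e-10, giving ~3e-8 agreement
between very different splittings).

The brute-force oracle sums point-dipole fields over concentric cubic
image shells. After adding the uniform surface term Σμ/(3V) that
separates the tinfoil from the vacuum/spherical convention, the shell
sums still converge only ~1/s²; the reference used in tests therefore
fits f(s) = f_∞ + A/s² + B/s³ over shells 8–16 and compares f_∞ to the
Ewald result (agreement ~1e-6 relative, with no code shared between the
two routes).

A quasi-static convention is used throughout: the sinusoidal external
field enters relaxation and field computations with its amplitude H₀.

## Energy landscape and barriers

With the easy axis as polar axis and the local field in the x–z plane at
angle ψ, the normalized free energy is
e(θ,φ) = σ sin²θ − ξ(cos ψ cos θ + sin ψ sin θ cos φ), σ = K_eff V/k_BT,
ξ = 2hσ, h = μ₀M_sH/2K_eff. All stationary points lie in the field
plane, where e(θ) = σ[sin²θ − 2h cos(θ−ψ)]. Below
h_c(ψ) = (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2} there are two minima
θ₁ < θ₂ separated by a saddle θ₀.

Numerics: ψ is folded into [0, π/2] (the landscape maps θ → π−θ, the
wells relabel); the derivative is bracketed on a 600-point grid (refined
to 20 000 near degeneracy) and each root polished by Brent's method to
1e-14. Angles and *reduced* barriers depend only on (ψ, h) — σ is a pure
scale factor — which the vectorized landscape exploits: a diameter sweep
at fixed seed reuses one field evaluation and one set of stationary
angles for every diameter, exactly (moments scale as d³ and distances as
d, leaving ψ and h unchanged).

For h ≥ 0.999 h_c the minima/saddle are numerically degenerate and the
particle is flagged as past criticality (`BistabilityLostError` in the
scalar API); ensemble averages exclude such particles and log their
count. At the validation-table field amplitude (24.5 kA/m) this excludes
roughly half to three quarters of a random-axis ensemble — those
parameter sets genuinely sit at the edge of the bistable regime.

Two barrier models:

* **Pfeiffer interpolation** (used by the discrete-orientation rate
  model): lower barrier σ(1−h/h_c)^{a_ψ} with a_ψ = 0.86 + 1.14 h_c.
  The upper barrier is the lower one plus the well asymmetry 2ξ cos ψ, a
  choice exact at ψ = 0 (σ(1±h)²) and at ψ = π/2 (degenerate wells);
  in between it approximates the true asymmetry to the same few-percent
  level as the Pfeiffer form itself.
* **Exact barriers** (used by the analytic model): energy differences
  e(θ₀) − e(θ_p) at the numerically located stationary points.

## Relaxation times

Both Néel models are two-state escape pictures, 1/τ_N = ν₁₂ + ν₂₁:

* discrete-orientation: ν = (1/τ₀) e^{−β}, τ₀ = 1e-9 s (attempt
  frequency 1e9 s⁻¹), Pfeiffer barriers.
* analytic: ν_p = (1/τ_pre) √(σ/π) |κ₀| κ_p e^{−β_p}, where
  κ(θ) = cos 2θ + h cos(θ−ψ) is the reduced in-plane curvature at the
  saddle (κ₀) and the departure minimum (κ_p). At ψ = 0 this is exactly
  the classical high-barrier asymptote for a longitudinal field,
  1/τ = (1/τ_pre)√(σ/π)(1−h²)[(1+h)e^{−σ(1+h)²} + (1−h)e^{−σ(1−h)²}].
  The default prefactor is the same constant τ₀ (the production choice);
  `prefactor_mode="free_diffusion"` instead uses the low-damping free
  diffusion time τ_D = M_sV(1+α²)/(2γα k_B T) with defaults α = 0.01,
  γ = 1.76e11 rad s⁻¹T⁻¹.

Because the analytic attempt rate carries √(σ/π), the two models
coincide at h = 0 only under a common pre-exponential convention (the
discrete τ₀ rescaled by √(π/σ)); the test suite checks the coincidence
in exactly that form. Known limitation: very close to h_c the curvature
product κ₀κ_p → 0 makes the asymptotic analytic rate vanish — an
artifact of the high-barrier expansion, not physics — so the analytic τ
is not monotone in h beyond ≈ 0.85 h_c, and near-critical particles can
carry unphysically long times into arithmetic averages.

Brownian rotation: τ_B = 3ηV_h/k_B T with the hydrodynamic volume;
effective time 1/τ_eff = 1/τ_N + 1/τ_B per particle.

**Ensemble averages** are arithmetic means of the per-particle times
(default), with `average="rate"` offered as a sensitivity switch
(harmonic mean). The arithmetic mean is dominated by the slowest
particles — at high concentration a few particles whose dipolar field
nearly cancels the applied field approach the zero-field time τ₀e^σ —
which makes some concentration trends noisy or even reversed relative
to typical-particle behaviour; the rate average conversely collapses
onto the fastest subpopulation. Both are reported honestly; neither is
tuned per result.

## Loss power

Equilibrium susceptibility χ₀ = κ r_V with κ = μ₀M_s²V_m/3k_BT; linear
in concentration. SLP per unit mass of magnetic material (density ρ of
the core material, 5180 kg/m³ for magnetite):

SLP = πμ₀κfH₀²/ρ · x/(1+x²), x = 2πf·τ_eff.

SLP is exactly quadratic in H₀ and unimodal in τ_eff with maximum at
x = 1 (τ = 5.305e-7 s at 300 kHz). For the validation table the measured
χ₀ of each sample is used as an input (its microscopic parameterization
is not recoverable from the printed sample data); elsewhere χ₀ is
computed. Cluster SLP uses the same expression with the cluster's local
fraction and mean effective time.

## Default study conditions

Magnetite: M_s = 4.46e5 A/m, K_eff = 2.5e4 J/m³, ρ = 5180 kg/m³;
water at T = 293 K, η = 8.9e-4 Pa·s; protocol H₀ = 15 kA/m,
f = 300 kHz; 1000-particle uniform systems and 50-particle clusters;
volume fractions 0.01–0.24; diameters 7–17 nm (sweeps 5–30 nm). The
validation samples override d, d_h, r_V, K_eff, H₀, f and χ₀ with the
printed sample values. Stochastic checks in the test suite use 300–500
particles and 10 seeds — sizes at which the orderings under test are
stable from seed to seed — while the end-to-end reproduction script
keeps the full 1000-particle, 5-seed protocol.

## Design choices where the design was open

* Site enumeration (vertices + face centres) as the default, strict BCC
  as an option.
* Moment configuration for the dipolar sum: nearest easy-axis minimum
  with non-negative field projection on the applied field. An optional
  relaxation loop (`self_consistent_moments`) re-points moments into the
  minimum selected by their *local* field, flipping one worst-misaligned
  moment per pass (synchronous updates oscillate on frustrated groups;
  single flips strictly lower the energy and must terminate). Off by
  default.
* Ewald surface term: tinfoil.
* Fixed exclusion threshold 0.999 h_c for lost bistability; chosen as a
  numerical-degeneracy guard, not calibrated against any output.
* Diameter-sweep optimum: grid argmax of seed-averaged SLP; ties return
  the first grid point with a warning, non-unimodal averaged curves log
  a warning.

## Known limitations

* The analytic model's asymptotic prefactor misbehaves within ~15 % of
  the critical field (see above); results there depend on the exclusion
  guard.
* Single average τ_eff in the Debye factor: the ensemble is compressed
  to one relaxation time before the loss is evaluated, so dispersion of
  per-particle times (which broadens the absorption line of a real
  sample) is not reflected in the SLP.
* Point dipoles only; no multipoles, no demagnetizing/shape corrections.
* Monodisperse size and anisotropy; no coating; no hysteretic (high
  field) losses — the model is meaningful only in the linear-response
  window.
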