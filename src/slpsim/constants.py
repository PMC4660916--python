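"""Physical constants used throughout the package (SI units)."""

#: Vacuum magnetic permeability, T·m/A.
MU0 = 4.0e-7 * 3.141592653589793

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Electron gyromagnetic ratio magnitude, rad·s⁻¹·T⁻¹ (default for the
#: free-diffusion prefactor; production runs use a constant attempt time).
GAMMA_E = 1.76e11
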