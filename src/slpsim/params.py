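"""Parameter containers: material, environment and AC-field protocol.

All quantities are SI.  The defaults correspond to uncoated magnetite
colloids in water, the system for which the package's relaxation and
loss-power models were calibrated: Ms = 4.46e5 A/m, K_eff = 2.5e4 J/m3,
rho = 5180 kg/m3, T = 293 K, eta = 8.9e-4 Pa·s, H0 = 15 kA/m, f = 300 kHz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_E


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class MaterialParams:
    """Magnetic material of the nanoparticle cores.

    Parameters
    ----------
    Ms : float
        Spontaneous (saturation) magnetization, A/m.
    K_eff : float
        Effective uniaxial anisotropy constant, J/m^3.
    rho : float
        Mass density of the magnetic material, kg/m^3.
    tau0 : float
        Attempt time of moment reversal (inverse attempt frequency), s.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1 (only used by the
        free-diffusion prefactor mode).
    alpha : float
        Dimensionless magnetic damping constant.  The analytic
        relaxation model assumes the low-damping regime (alpha << 1);
        a warning is emitted for alpha >= 0.1.
    """

    Ms: float = 4.46e5
    K_eff: float = 2.5e4
    rho: float = 5180.0
    tau0: float = 1.0e-9
    gamma: float = GAMMA_E
    alpha: float = 0.01

    def __post_init__(self):
        for name in ("Ms", "K_eff", "rho", "tau0", "gamma", "alpha"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha >= 0.1:
            warnings.warn(
                f"alpha = {self.alpha} is outside the low-damping regime "
                "(alpha << 1) assumed by the analytic relaxation model",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Environment:
    """Carrier-fluid environment: temperature and dynamic viscosity."""

    T: float = 293.0
    eta: float = 8.9e-4

    def __post_init__(self):
        if not self.T > 0.0:
            raise ValueError("T must be strictly positive")
        if not self.eta > 0.0:
            raise ValueError("eta must be strictly positive")


@dataclass(frozen=True)
class FieldProtocol:
    """Sinusoidal external field: amplitude H0 (A/m), frequency f (Hz),
    and direction (unit vector; the +z convention is used throughout)."""

    H0: float = 15.0e3
    f: float = 300.0e3
    direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.H0 < 0.0:
            raise ValueError("H0 must be non-negative")
        if not self.f > 0.0:
            raise ValueError("f must be strictly positive")
        d = _unit(self.direction)
        object.__setattr__(self, "direction", tuple(float(x) for x in d))
        if not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=1e-12):
            raise ValueError("direction must normalize to a unit vector")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*f, rad/s."""
        return 2.0 * math.pi * self.f

    @property
    def direction_array(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)
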