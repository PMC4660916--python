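"""Equilibrium susceptibility and specific loss power via linear response.

The volumetric loss power of a ferrofluid in a sinusoidal field of
amplitude H0 and frequency f is the Debye out-of-phase response

    P = pi mu_0 chi_0 f H0^2 * (omega tau_eff) / (1 + (omega tau_eff)^2),

with omega = 2 pi f and chi_0 the equilibrium susceptibility

    chi_0 = kappa r_V,     kappa = mu_0 Ms^2 V_m / (3 k_B T),

linear in the volume fraction r_V (V_m is the mean particle core volume).
The specific loss power per unit mass of magnetic material divides P by
rho r_V (the magnetic mass per unit fluid volume), so

    SLP = pi mu_0 kappa f H0^2 / rho * (omega tau) / (1 + (omega tau)^2)

in W/kg.  SLP is exactly quadratic in H0 and unimodal in tau_eff with its
maximum at omega tau_eff = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .constants import KB, MU0
from .ensemble import Ensemble
from .params import Environment, FieldProtocol, MaterialParams
from .relaxation import RelaxationSummary


@dataclass(frozen=True)
class SLPResult:
    """One SLP evaluation and the coordinates that produced it."""

    chi0: float
    slp: float  # W per kg of magnetic material
    r_V: float
    d: float
    f: float
    H0: float
    model: str
    axes_mode: str
    tau_eff: float
    r_V_loc: Optional[float] = None


def susceptibility_prefactor(
    material: MaterialParams, env: Environment, V_m: float
) -> float:
    """kappa = mu_0 Ms^2 V_m / (3 k_B T): the susceptibility per unit
    volume fraction (dimensionless)."""
    if not V_m > 0:
        raise ValueError("mean particle volume must be positive")
    return MU0 * material.Ms**2 * V_m / (3.0 * KB * env.T)


def equilibrium_susceptibility(
    material: MaterialParams, env: Environment, V_m: float, r_V: float
) -> float:
    """Equilibrium susceptibility chi_0 = kappa * r_V of the assembly."""
    if r_V < 0:
        raise ValueError("volume fraction must be non-negative")
    return susceptibility_prefactor(material, env, V_m) * r_V


def debye_factor(tau: float, f: float) -> float:
    """Out-of-phase dispersion factor x/(1+x^2) with x = 2 pi f tau."""
    x = 2.0 * math.pi * f * tau
    return x / (1.0 + x * x)


def slp_lrt(
    chi0: float,
    tau_eff: float,
    protocol: FieldProtocol,
    material: MaterialParams,
    r_V: float,
) -> float:
    """Specific loss power (W per kg of magnetic material) from linear
    response theory, for an assembly of susceptibility ``chi0`` at volume
    fraction ``r_V`` with mean effective relaxation time ``tau_eff``."""
    if not tau_eff > 0:
        raise ValueError("tau_eff must be positive")
    if not r_V > 0:
        raise ValueError("r_V must be positive")
    kappa = chi0 / r_V
    return (
        math.pi
        * MU0
        * kappa
        * protocol.f
        * protocol.H0**2
        / material.rho
        * debye_factor(tau_eff, protocol.f)
    )


def slp_cluster(
    cluster: Ensemble,
    summary: RelaxationSummary,
    protocol: FieldProtocol,
    material: MaterialParams,
    env: Environment,
) -> SLPResult:
    """Local SLP of a dense cluster, reported against its local volume
    fraction r_V_loc: the cluster's local susceptibility kappa * r_V_loc
    and its mean effective time enter the same mass-normalized Debye
    expression as the uniform system."""
    if cluster.r_V_loc is None:
        raise ValueError("cluster ensemble has no recorded r_V_loc")
    V_m = float(cluster.volumes.mean())
    chi0 = susceptibility_prefactor(material, env, V_m) * cluster.r_V_loc
    value = slp_lrt(chi0, summary.mean_tau_eff, protocol, material, cluster.r_V_loc)
    return SLPResult(
        chi0=chi0,
        slp=value,
        r_V=cluster.r_V,
        r_V_loc=cluster.r_V_loc,
        d=float(cluster.core_diameters.mean()),
        f=protocol.f,
        H0=protocol.H0,
        model=summary.model,
        axes_mode=summary.axes_mode,
        tau_eff=summary.mean_tau_eff,
    )
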