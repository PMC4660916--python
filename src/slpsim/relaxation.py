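"""Néel, Brownian and effective relaxation times.

Two Néel-time models share the two-state rate picture
1/tau_N = nu_12 + nu_21 (escape over either barrier):

* ``discrete`` — Arrhenius rates nu = (1/tau0) exp(-beta) with the
  Pfeiffer closed-form barriers; this is the classical discrete-orientation
  approximation.
* ``coffey`` — the analytic oblique-field model: exact stationary-point
  barriers with curvature-corrected attempt rates

      nu_p = (1/tau_pre) sqrt(sigma/pi) |kappa_0| kappa_p exp(-beta_p),

  where kappa are the reduced in-plane curvatures at the saddle and the
  departure minimum.  At psi = 0 this reduces to the classical asymptote
  (1/tau) = (1/tau_pre) sqrt(sigma/pi) (1-h^2) [(1+h) e^{-sigma(1+h)^2}
  + (1-h) e^{-sigma(1-h)^2}] for a longitudinal field.

``tau_pre`` is the constant attempt time tau0 = 1e-9 s by default
(``prefactor_mode="constant_tau0"``); ``"free_diffusion"`` instead uses the
low-damping free-diffusion time tau_D = Ms V (1+alpha^2)/(2 gamma alpha
k_B T), expressed through sigma as Ms sigma (1+alpha^2)/(2 gamma alpha
K_eff).

The Brownian time is tau_B = 3 eta V_h / (k_B T) and the effective time the
harmonic combination 1/tau_eff = 1/tau_N + 1/tau_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .barriers import BarrierSet, reduced_landscape
from .constants import KB
from .dipolar import LocalFieldState
from .ensemble import Ensemble
from .params import Environment, FieldProtocol, MaterialParams

_SQRT_PI = math.sqrt(math.pi)

MODELS = ("discrete", "coffey")


def neel_time_discrete(barriers: BarrierSet, tau0: float) -> float:
    """Discrete-orientation Néel time: inverse sum of the two Arrhenius
    escape rates, tau_N = tau0 / (exp(-beta1) + exp(-beta2))."""
    return tau0 / (math.exp(-barriers.beta1) + math.exp(-barriers.beta2))


def free_diffusion_time(sigma: float, material: MaterialParams) -> float:
    """Low-damping free-diffusion magnetization time tau_D =
    Ms V (1 + alpha^2) / (2 gamma alpha k_B T), s."""
    a = material.alpha
    return (
        material.Ms * sigma * (1.0 + a * a)
        / (2.0 * material.gamma * a * material.K_eff)
    )


def neel_time_coffey(
    psi: float,
    h: float,
    sigma: float,
    material: MaterialParams,
    prefactor_mode: str = "constant_tau0",
) -> float:
    """Analytic (adapted Coffey) Néel time under an oblique reduced field.

    Requires h < h_c(psi); raises :class:`BistabilityLostError` otherwise.
    """
    land = reduced_landscape(np.array([psi]), np.array([h]))
    if not land["valid"][0]:
        from .barriers import BistabilityLostError

        raise BistabilityLostError(
            f"h = {h:.6g} at or beyond the critical field for psi = {psi:.6g}"
        )
    tau = _coffey_times(land, np.array([sigma]), _prefactor(material, prefactor_mode, sigma))
    return float(tau[0])


def _prefactor(material: MaterialParams, mode: str, sigma) -> np.ndarray:
    if mode == "constant_tau0":
        return np.broadcast_to(material.tau0, np.shape(sigma)) if np.ndim(sigma) else material.tau0
    if mode == "free_diffusion":
        a = material.alpha
        return material.Ms * np.asarray(sigma) * (1.0 + a * a) / (
            2.0 * material.gamma * a * material.K_eff
        )
    raise ValueError(f"unknown prefactor mode {mode!r}")


def _coffey_times(land: dict, sigma: np.ndarray, tau_pre) -> np.ndarray:
    b1 = sigma * land["b1_hat"]
    b2 = sigma * land["b2_hat"]
    pref = np.sqrt(sigma / math.pi) * np.abs(land["kappa0"])
    rate = (
        pref
        * (land["kappa1"] * np.exp(-b1) + land["kappa2"] * np.exp(-b2))
        / tau_pre
    )
    return 1.0 / rate


def _discrete_times(land: dict, sigma: np.ndarray, tau0: float) -> np.ndarray:
    b1 = sigma * land["b1_pf"]
    b2 = sigma * land["b2_pf"]
    return tau0 / (np.exp(-b1) + np.exp(-b2))


def neel_times_from_landscape(
    land: dict,
    sigma: np.ndarray,
    material: MaterialParams,
    model: str,
    prefactor_mode: str = "constant_tau0",
) -> np.ndarray:
    """Vectorized per-particle Néel times from a precomputed reduced
    landscape (see :func:`slpsim.barriers.reduced_landscape`); NaN where the
    bistability condition fails."""
    sigma = np.asarray(sigma, dtype=float)
    if model == "discrete":
        return _discrete_times(land, sigma, material.tau0)
    if model == "coffey":
        return _coffey_times(land, sigma, _prefactor(material, prefactor_mode, sigma))
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def brownian_time(V_h: float, env: Environment) -> float:
    """Brownian rotational relaxation time tau_B = 3 eta V_h / (k_B T), s."""
    if not V_h > 0:
        raise ValueError("hydrodynamic volume must be positive")
    return 3.0 * env.eta * V_h / (KB * env.T)


def effective_time(tau_N, tau_B):
    """Harmonic combination 1/tau_eff = 1/tau_N + 1/tau_B."""
    tau_N = np.asarray(tau_N, dtype=float)
    out = 1.0 / (1.0 / tau_N + 1.0 / tau_B)
    return float(out) if out.ndim == 0 else out


@dataclass
class RelaxationSummary:
    """Per-particle and ensemble-averaged relaxation times for one model.

    ``tau_N``/``tau_eff`` are per-particle arrays with NaN for particles
    past the critical field; those particles are excluded from the means
    and counted in ``n_excluded``.
    """

    tau_N: np.ndarray
    tau_B: float
    tau_eff: np.ndarray
    mean_tau_N: float
    mean_tau_eff: float
    model: str
    axes_mode: str = "unspecified"
    n_excluded: int = 0
    valid: np.ndarray = field(default=None, repr=False)
    average: str = "time"


def ensemble_relaxation(
    ensemble: Ensemble,
    states: LocalFieldState,
    model: str,
    protocol: FieldProtocol,
    material: MaterialParams,
    env: Environment,
    *,
    prefactor_mode: str = "constant_tau0",
    average: str = "time",
    axes_mode: str = "unspecified",
    landscape: Optional[dict] = None,
) -> RelaxationSummary:
    """Per-particle Néel and effective times plus ensemble averages.

    ``average="time"`` takes arithmetic means of the per-particle times
    (the default); ``average="rate"`` averages rates instead (harmonic
    mean of times), offered for sensitivity analysis.
    """
    if average not in ("time", "rate"):
        raise ValueError("average must be 'time' or 'rate'")
    land = landscape if landscape is not None else reduced_landscape(states.psi, states.h)
    tau_N = neel_times_from_landscape(
        land, states.sigma, material, model, prefactor_mode
    )
    # shared Brownian time for the monodisperse hydrodynamic size
    tau_B = brownian_time(float(ensemble.hydro_volumes[0]), env)
    tau_eff = effective_time(tau_N, tau_B)
    valid = land["valid"] & np.isfinite(tau_N)
    n_excl = int(ensemble.n - valid.sum())
    if valid.any():
        if average == "time":
            mean_N = float(np.mean(tau_N[valid]))
            mean_eff = float(np.mean(tau_eff[valid]))
        else:
            mean_N = float(1.0 / np.mean(1.0 / tau_N[valid]))
            mean_eff = float(1.0 / np.mean(1.0 / tau_eff[valid]))
    else:
        mean_N = math.nan
        mean_eff = math.nan
    return RelaxationSummary(
        tau_N=tau_N,
        tau_B=tau_B,
        tau_eff=tau_eff,
        mean_tau_N=mean_N,
        mean_tau_eff=mean_eff,
        model=model,
        axes_mode=axes_mode,
        n_excluded=n_excl,
        valid=valid,
        average=average,
    )
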