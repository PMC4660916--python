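"""Energy landscape of a uniaxial particle in an oblique local field.

The normalized (over k_B T) free energy of a moment at polar angle theta,
azimuth phi (polar axis = easy axis, field in the x–z plane at angle psi
from the axis) is

    e(theta, phi) = sigma sin^2(theta)
                    - xi [cos(psi) cos(theta) + sin(psi) sin(theta) cos(phi)],

with sigma = K_eff V / (k_B T) and xi = mu_0 Ms V H / (k_B T) = 2 h sigma.
All stationary points lie in the field plane (phi = 0), where

    e(theta) = sigma [ sin^2(theta) - 2 h cos(theta - psi) ].

For h below the critical reduced field h_c(psi) = (cos^{2/3}psi +
sin^{2/3}psi)^{-3/2} the landscape is bistable: two minima theta_1 <
theta_2 separated by a saddle theta_0.  Barriers are reported normalized
over k_B T.

Two barrier models are provided:

* ``pfeiffer_barriers`` — the closed-form interpolation for the lower
  barrier, sigma (1 - h/h_c)^{a_psi} with a_psi = 0.86 + 1.14 h_c, exact at
  psi = 0 and psi = pi/2; the upper barrier adds the well asymmetry
  2 xi cos(psi) (exact in the same two limits).
* ``coffey_barriers`` — exact energy differences evaluated at the
  numerically located stationary angles.

Because e(theta) = sigma * e_hat(theta; h, psi), stationary angles and the
*reduced* barriers e_hat depend on (psi, h) only; sigma enters as a pure
scale factor.  The vectorized ``reduced_landscape`` exploits this for
whole-ensemble and diameter-sweep computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

_HC_GUARD = 0.999  # beyond this fraction of h_c the wells are numerically degenerate


class BistabilityLostError(ValueError):
    """The reduced field reaches or exceeds the critical field h_c(psi):
    the two-well structure (and with it any barrier) is lost."""


@dataclass(frozen=True)
class BarrierSet:
    """Stationary angles (rad) and normalized barriers of one particle.

    ``beta1`` is the barrier seen from the deep minimum ``theta1``,
    ``beta2`` the (lower) barrier from the shallow minimum ``theta2``;
    ``lower`` names which of the two is smaller.
    """

    theta1: float
    theta2: float
    theta0: float
    beta1: float
    beta2: float
    h_c: float
    model: str  # "pfeiffer" | "coffey_analytic"

    @property
    def lower(self) -> float:
        return min(self.beta1, self.beta2)

    @property
    def upper(self) -> float:
        return max(self.beta1, self.beta2)


def critical_field(psi) -> float | np.ndarray:
    """Critical reduced field h_c = (cos^{2/3}psi + sin^{2/3}psi)^{-3/2};
    quadrants outside [0, pi/2] are folded by the landscape symmetry."""
    psi = np.abs(np.asarray(psi, dtype=float))
    psi = np.where(psi > math.pi / 2.0, math.pi - psi, psi)
    c = np.abs(np.cos(psi)) ** (2.0 / 3.0) + np.abs(np.sin(psi)) ** (2.0 / 3.0)
    out = c**-1.5
    return float(out) if out.ndim == 0 else out


def free_energy(theta, phi, psi: float, sigma: float, xi: float):
    """Normalized free energy e(theta, phi) (dimensionless, over k_B T)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(theta), np.cos(theta)
    out = sigma * st**2 - xi * (
        math.cos(psi) * ct + math.sin(psi) * st * np.cos(phi)
    )
    return float(out) if out.ndim == 0 else out


def _e_hat(theta, psi: float, h: float):
    """In-plane reduced energy e/sigma = sin^2 - 2h cos(theta - psi)."""
    return np.sin(theta) ** 2 - 2.0 * h * np.cos(theta - psi)


def _g(theta: float, psi: float, h: float) -> float:
    """Half derivative of the reduced in-plane energy."""
    return 0.5 * math.sin(2.0 * theta) + h * math.sin(theta - psi)


def curvature(theta, psi: float, h: float):
    """Reduced in-plane curvature e''/(2 sigma) = cos(2 theta)
    + h cos(theta - psi); positive at minima, negative at the saddle."""
    return np.cos(2.0 * np.asarray(theta, dtype=float)) + h * np.cos(
        np.asarray(theta, dtype=float) - psi
    )


def _stationary_folded(psi: float, h: float) -> tuple[float, float, float]:
    """Stationary angles for psi already folded into [0, pi/2]."""
    hc = float(critical_field(psi))
    if h >= _HC_GUARD * hc:
        raise BistabilityLostError(
            f"h = {h:.6g} >= {_HC_GUARD} * h_c(psi) = {_HC_GUARD * hc:.6g}: "
            "the energy landscape is (numerically) monostable"
        )
    if h < 1e-14:
        return 0.0, math.pi / 2.0, math.pi
    if psi < 1e-12:
        return 0.0, math.acos(-h), math.pi
    if math.pi / 2.0 - psi < 1e-12:
        return math.asin(h), math.pi / 2.0, math.pi - math.asin(h)
    # generic case: g starts negative at 0, ends positive at pi, with
    # exactly three sign changes (-+, +-, -+) below h_c
    grid = np.linspace(0.0, math.pi, 600)
    vals = 0.5 * np.sin(2.0 * grid) + h * np.sin(grid - psi)
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) != 3:
        # refine: degenerate roots near merging extrema
        grid = np.linspace(0.0, math.pi, 20000)
        vals = 0.5 * np.sin(2.0 * grid) + h * np.sin(grid - psi)
        sign = np.sign(vals)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if len(idx) != 3:
            raise BistabilityLostError(
                f"could not bracket three stationary points at psi={psi}, h={h}"
            )
    roots = [
        brentq(_g, grid[i], grid[i + 1], args=(psi, h), xtol=1e-14, rtol=8.9e-16)
        for i in idx
    ]
    return roots[0], roots[1], roots[2]


def _fold(psi: float) -> tuple[float, bool]:
    psi = abs(float(psi)) % math.pi
    if psi > math.pi / 2.0:
        return math.pi - psi, True
    return psi, False


def stationary_angles(psi: float, h: float, sigma: float = 1.0):
    """The two minima and the saddle of the in-plane energy, as
    (theta1, theta2, theta0) with 0 <= theta1 < theta0 < theta2 <= pi.

    Raises :class:`BistabilityLostError` for h >= 0.999 h_c(psi).
    ``sigma`` is accepted for interface symmetry; the angles are
    independent of it.
    """
    if h < 0.0:
        raise ValueError("reduced field h must be non-negative")
    psi_f, folded = _fold(psi)
    t1, t0, t2 = _stationary_folded(psi_f, h)
    if folded:
        t1, t0, t2 = math.pi - t2, math.pi - t0, math.pi - t1
    return t1, t2, t0


def coffey_barriers(psi: float, h: float, sigma: float) -> BarrierSet:
    """Exact normalized barriers: energy differences between the saddle and
    each minimum of the in-plane landscape (the analytic model's barriers)."""
    psi_f, folded = _fold(psi)
    hc = float(critical_field(psi_f))
    t1, t0, t2 = _stationary_folded(psi_f, h)
    e1, e0, e2 = (_e_hat(t, psi_f, h) for t in (t1, t0, t2))
    b1 = sigma * float(e0 - e1)
    b2 = sigma * float(e0 - e2)
    if folded:
        t1, t0, t2 = math.pi - t2, math.pi - t0, math.pi - t1
        b1, b2 = b2, b1
    return BarrierSet(
        theta1=t1, theta2=t2, theta0=t0, beta1=b1, beta2=b2, h_c=hc,
        model="coffey_analytic",
    )


def pfeiffer_exponent(psi) -> float | np.ndarray:
    """Interpolation exponent a_psi = 0.86 + 1.14 h_c(psi)."""
    return 0.86 + 1.14 * critical_field(psi)


def pfeiffer_barriers(psi: float, h: float, sigma: float) -> BarrierSet:
    """Closed-form approximate barriers.

    Lower barrier sigma (1 - h/h_c)^{a_psi}; upper barrier obtained by
    adding the well asymmetry 2 xi cos(psi) (with xi = 2 h sigma), which
    reproduces the exact sigma (1 -/+ h)^2 pair at psi = 0 and the
    symmetric sigma (1 - h)^2 pair at psi = pi/2."""
    psi_f, folded = _fold(psi)
    hc = float(critical_field(psi_f))
    if h >= _HC_GUARD * hc:
        raise BistabilityLostError(
            f"h = {h:.6g} >= {_HC_GUARD} * h_c(psi) = {_HC_GUARD * hc:.6g}"
        )
    a = 0.86 + 1.14 * hc
    b_low = sigma * (1.0 - h / hc) ** a
    b_high = b_low + 4.0 * sigma * h * math.cos(psi_f)
    t1, t0, t2 = _stationary_folded(psi_f, h)
    b1, b2 = b_high, b_low
    if folded:
        t1, t0, t2 = math.pi - t2, math.pi - t0, math.pi - t1
        b1, b2 = b2, b1
    return BarrierSet(
        theta1=t1, theta2=t2, theta0=t0, beta1=b1, beta2=b2, h_c=hc,
        model="pfeiffer",
    )


def reduced_landscape(psi: np.ndarray, h: np.ndarray) -> dict:
    """Vectorized landscape summary for arrays of (psi, h).

    Returns a dict of arrays: stationary angles ``theta1/theta0/theta2``
    (folded frame), exact reduced barriers ``b1_hat``/``b2_hat`` (multiply
    by sigma to get beta), Pfeiffer reduced barriers ``b1_pf``/``b2_pf``,
    in-plane curvatures ``kappa1/kappa2/kappa0`` at the stationary points,
    ``h_c`` and a boolean ``valid`` marking particles below the
    bistability guard.  Invalid entries hold NaN.

    sigma never enters: beta = sigma * b_hat, so one landscape evaluation
    serves every particle volume (e.g. a whole diameter sweep).
    """
    psi = np.asarray(psi, dtype=float)
    h = np.asarray(h, dtype=float)
    psi_f = np.where(psi > math.pi / 2.0, math.pi - psi, psi)
    hc = critical_field(psi_f)
    valid = h < _HC_GUARD * hc
    n = psi.shape[0]
    out = {
        k: np.full(n, np.nan)
        for k in (
            "theta1", "theta0", "theta2", "b1_hat", "b2_hat",
            "b1_pf", "b2_pf", "kappa1", "kappa2", "kappa0",
        )
    }
    out["h_c"] = hc
    out["valid"] = valid
    a = 0.86 + 1.14 * hc
    for i in np.nonzero(valid)[0]:
        t1, t0, t2 = _stationary_folded(float(psi_f[i]), float(h[i]))
        e1, e0, e2 = (_e_hat(t, psi_f[i], h[i]) for t in (t1, t0, t2))
        out["theta1"][i], out["theta0"][i], out["theta2"][i] = t1, t0, t2
        out["b1_hat"][i] = e0 - e1
        out["b2_hat"][i] = e0 - e2
        out["kappa1"][i] = curvature(t1, psi_f[i], h[i])
        out["kappa2"][i] = curvature(t2, psi_f[i], h[i])
        out["kappa0"][i] = curvature(t0, psi_f[i], h[i])
    b_low = np.where(valid, np.clip(1.0 - h / hc, 0.0, None) ** a, np.nan)
    out["b2_pf"] = b_low
    out["b1_pf"] = b_low + 4.0 * h * np.cos(psi_f)
    return out
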