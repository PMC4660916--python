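import math

import numpy as np
import pytest

from slpsim import (
    BistabilityLostError,
    FieldProtocol,
    MaterialParams,
    brownian_time,
    build_uniform_ensemble,
    coffey_barriers,
    effective_time,
    ensemble_relaxation,
    free_diffusion_time,
    initialize_moments,
    local_fields,
    neel_time_coffey,
    neel_time_discrete,
    pfeiffer_barriers,
)
from slpsim.params import Environment


def test_discrete_time_symmetric_barriers():
    """Equal barriers sigma = 10: tau = tau0 e^sigma / 2 = 1.101e-5 s."""
    b = pfeiffer_barriers(0.3, 0.0, 10.0)
    tau = neel_time_discrete(b, 1e-9)
    assert tau == pytest.approx(1e-9 * math.exp(10) / 2, rel=1e-12)
    assert tau == pytest.approx(1.101e-5, rel=1e-3)


def test_discrete_time_small_barrier():
    b = pfeiffer_barriers(0.0, 0.0, 1.1097)
    assert neel_time_discrete(b, 1e-9) == pytest.approx(1.517e-9, rel=1e-3)


def test_brownian_time_values(env):
    """tau_B = 3 eta V_h/(k_B T): 6.07e-6 s at 26 nm, 1.19e-7 s at 7 nm."""
    Vh = lambda d: (math.pi / 6) * d**3
    assert brownian_time(Vh(26e-9), env) == pytest.approx(6.07e-6, rel=2e-3)
    assert brownian_time(Vh(7e-9), env) == pytest.approx(1.19e-7, rel=5e-3)
    doubled = Environment(T=env.T, eta=2 * env.eta)
    assert brownian_time(Vh(7e-9), doubled) == pytest.approx(
        2 * brownian_time(Vh(7e-9), env), rel=1e-14
    )


def test_effective_time_harmonic():
    assert effective_time(2e-6, 2e-6) == pytest.approx(1e-6, rel=1e-14)
    assert effective_time(1.517e-9, 1.185e-7) == pytest.approx(1.498e-9, rel=1e-3)
    assert effective_time(3.3e-9, 1e12) == pytest.approx(3.3e-9, rel=1e-9)


def test_models_coincide_at_zero_field(material):
    """At h = 0 the analytic rate is (1/tau0) sqrt(sigma/pi) * 2 e^-sigma;
    with the discrete attempt time rescaled by sqrt(pi/sigma) (the common
    prefactor convention) the two models agree to 1e-10."""
    for sigma in (2.0, 10.0, 25.0):
        for psi in (0.0, 0.7, math.pi / 2):
            tc = neel_time_coffey(psi, 0.0, sigma, material)
            b = pfeiffer_barriers(psi, 0.0, sigma)
            td = neel_time_discrete(b, material.tau0 * math.sqrt(math.pi / sigma))
            assert tc == pytest.approx(td, rel=1e-10)


def test_coffey_axial_matches_classical_asymptote(material):
    """psi = 0 reduces to (1/tau) = (1/tau0) sqrt(sigma/pi) (1-h^2)
    [(1+h) e^{-sigma(1+h)^2} + (1-h) e^{-sigma(1-h)^2}]."""
    sigma, h = 8.0, 0.3
    rate = (
        math.sqrt(sigma / math.pi)
        * (1 - h**2)
        * (
            (1 + h) * math.exp(-sigma * (1 + h) ** 2)
            + (1 - h) * math.exp(-sigma * (1 - h) ** 2)
        )
        / material.tau0
    )
    assert neel_time_coffey(0.0, h, sigma, material) == pytest.approx(1 / rate, rel=1e-10)


def test_coffey_monotone_decreasing_in_h(material):
    """tau decreases as the reduced field grows (psi = pi/4, sigma = 15.90),
    across the asymptote's validity range h <= 0.8 h_c."""
    hs = np.linspace(0.0, 0.8 * 0.5, 30)
    taus = [neel_time_coffey(math.pi / 4, float(h), 15.90, material) for h in hs]
    assert all(a > b for a, b in zip(taus, taus[1:]))


def test_coffey_diameter_dependence(material, env):
    """tau(17 nm) >> tau(7 nm) at equal reduced field geometry."""
    kT = 1.380649e-23 * env.T
    sig = lambda d: material.K_eff * (math.pi / 6) * d**3 / kT
    t7 = neel_time_coffey(0.5, 0.1, sig(7e-9), material)
    t17 = neel_time_coffey(0.5, 0.1, sig(17e-9), material)
    assert t17 > 100 * t7


def test_coffey_bistability_error(material):
    with pytest.raises(BistabilityLostError):
        neel_time_coffey(math.pi / 4, 0.55, 10.0, material)


def test_free_diffusion_prefactor(material):
    """tau_D = Ms V (1+a^2)/(2 gamma a k_B T), expressed through sigma."""
    sigma = 5.0
    tau_D = free_diffusion_time(sigma, material)
    V_over_kT = sigma / material.K_eff
    expected = material.Ms * V_over_kT * (1 + material.alpha**2) / (
        2 * material.gamma * material.alpha
    )
    assert tau_D == pytest.approx(expected, rel=1e-14)
    tau_const = neel_time_coffey(0.3, 0.1, sigma, material, "constant_tau0")
    tau_fd = neel_time_coffey(0.3, 0.1, sigma, material, "free_diffusion")
    assert tau_fd / tau_const == pytest.approx(tau_D / material.tau0, rel=1e-12)


def test_ensemble_relaxation_zero_field_reduction(material, env):
    """Single particle, parallel axis, H0 = 0: the discrete mean time is the
    symmetric two-state value tau0 e^sigma / 2."""
    ens = build_uniform_ensemble(1, 1e-4, 7e-9, material, seed=0)
    ens = initialize_moments(ens, [0, 0, 1])
    protocol = FieldProtocol(H0=0.0, f=300e3)
    st = local_fields(ens, protocol, material, env)
    summary = ensemble_relaxation(ens, st, "discrete", protocol, material, env)
    sigma = st.sigma[0]
    assert summary.mean_tau_N == pytest.approx(material.tau0 * math.exp(sigma) / 2, rel=1e-5)
    assert summary.n_excluded == 0


def test_ensemble_relaxation_harmonic_identity(small_periodic, material, env, protocol):
    ens = small_periodic(seed=3, n=8)
    st = local_fields(ens, protocol, material, env)
    for model in ("discrete", "coffey"):
        s = ensemble_relaxation(ens, st, model, protocol, material, env)
        ok = s.valid
        lhs = 1.0 / s.tau_eff[ok]
        rhs = 1.0 / s.tau_N[ok] + 1.0 / s.tau_B
        assert np.allclose(lhs, rhs, rtol=1e-12)
        assert np.all(s.tau_eff[ok] <= np.minimum(s.tau_N[ok], s.tau_B) * (1 + 1e-12))


def test_ensemble_relaxation_excludes_supercritical(material, env):
    """Particles driven past h_c are excluded from the means and counted."""
    ens = build_uniform_ensemble(1, 1e-4, 17e-9, material, seed=0)
    ens = initialize_moments(ens, [0, 0, 1])
    # field at 45 degrees to the axis, strong enough that h > h_c = 0.5
    protocol = FieldProtocol(H0=1.2e5, f=300e3, direction=(1, 0, 1))
    st = local_fields(ens, protocol, material, env)
    s = ensemble_relaxation(ens, st, "coffey", protocol, material, env)
    assert s.n_excluded == 1
    assert math.isnan(s.mean_tau_N)


def test_rate_averaging_switch(small_periodic, material, env, protocol):
    ens = small_periodic(seed=1, n=8)
    st = local_fields(ens, protocol, material, env)
    t = ensemble_relaxation(ens, st, "discrete", protocol, material, env, average="time")
    r = ensemble_relaxation(ens, st, "discrete", protocol, material, env, average="rate")
    ok = t.valid
    assert t.mean_tau_N == pytest.approx(float(np.mean(t.tau_N[ok])), rel=1e-14)
    assert r.mean_tau_N == pytest.approx(float(1 / np.mean(1 / t.tau_N[ok])), rel=1e-14)
    assert r.mean_tau_N <= t.mean_tau_N  # harmonic <= arithmetic
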