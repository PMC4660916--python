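import math

import numpy as np
import pytest

from slpsim import (
    EwaldParams,
    build_uniform_ensemble,
    dipolar_energy,
    direct_dipolar_field,
    ewald_dipolar_field,
    initialize_moments,
    local_fields,
    shell_extrapolated_dipolar_field,
    surface_term,
)
from slpsim.constants import MU0

from conftest import make_pair


def test_single_particle_open_boundary_field_is_zero(material):
    ens = make_pair(material, 30e-9, [0, 0, 1], [[0, 0, 1], [0, 0, 1]])
    single = build_uniform_ensemble(1, 0.05, 17e-9, material, seed=0)
    single.boundary = "open"
    assert np.allclose(direct_dipolar_field(single, 0, 0), 0.0)


def test_two_dipole_axial_closed_form(material):
    """Two +z moments 30 nm apart along z: each sees 2 mu/(4 pi r^3),
    about 6.76e3 A/m, along +z."""
    ens = make_pair(material, 30e-9, [0, 0, 1], [[0, 0, 1], [0, 0, 1]], d=17e-9)
    mu = material.Ms * (math.pi / 6) * (17e-9) ** 3
    expected = 2 * mu / (4 * math.pi * (30e-9) ** 3)
    assert 6.7e3 < expected < 6.8e3
    for i in (0, 1):
        H = direct_dipolar_field(ens, i, 0)
        assert np.allclose(H, [0, 0, expected], rtol=1e-12)


def test_two_dipole_perpendicular_closed_form(material):
    """Moments perpendicular to the separation: each sees -mu/(4 pi r^3)."""
    ens = make_pair(material, 30e-9, [1, 0, 0], [[0, 0, 1], [0, 0, 1]], d=17e-9)
    mu = material.Ms * (math.pi / 6) * (17e-9) ** 3
    expected = -mu / (4 * math.pi * (30e-9) ** 3)
    for i in (0, 1):
        assert np.allclose(direct_dipolar_field(ens, i, 0), [0, 0, expected], rtol=1e-12)


def test_antiparallel_pair_antisymmetry(material):
    ens = make_pair(material, 25e-9, [0, 1, 0], [[0, 0, 1], [0, 0, -1]])
    H0 = direct_dipolar_field(ens, 0, 0)
    H1 = direct_dipolar_field(ens, 1, 0)
    assert np.allclose(H0, -H1, rtol=1e-12)


def test_coincident_positions_error(material):
    ens = make_pair(material, 25e-9, [0, 1, 0], [[0, 0, 1], [0, 0, 1]])
    ens.positions[1] = ens.positions[0]
    with pytest.raises(ValueError, match="coincident"):
        direct_dipolar_field(ens, 0, 0)


def test_ewald_requires_periodic(material):
    ens = make_pair(material, 25e-9, [0, 1, 0], [[0, 0, 1], [0, 0, 1]])
    with pytest.raises(ValueError, match="direct_dipolar_field"):
        ewald_dipolar_field(ens)


def test_ewald_single_particle_self_image_field(material):
    """One dipole in a periodic box: the cubic-shell direct sum vanishes by
    symmetry, so the tinfoil result is exactly the surface term mu/(3V)."""
    ens = build_uniform_ensemble(1, 0.05, 10e-9, material, seed=0)
    ens = initialize_moments(ens, [0, 0, 1])
    ew = ewald_dipolar_field(ens, EwaldParams.for_box(ens.box_length, 1e-10))
    shells = direct_dipolar_field(ens, 0, 8)
    assert np.allclose(shells, 0.0, atol=1e-9 * abs(ew).max())
    expected = shells + surface_term(ens)
    assert np.allclose(ew[0], expected, rtol=1e-6)


@pytest.mark.parametrize("seed", range(20))
def test_ewald_matches_direct_image_sums(small_periodic, seed):
    """Ewald equals the (shell-extrapolated) direct image sum to 1e-5
    relative on small periodic fixtures, across 20 seeds."""
    ens = small_periodic(seed=seed, n=5 + seed % 4)
    ew = ewald_dipolar_field(ens, EwaldParams.for_box(ens.box_length, 1e-10))
    oracle = shell_extrapolated_dipolar_field(ens)
    assert np.abs(ew - oracle).max() <= 1e-5 * np.abs(oracle).max()


def test_translation_invariance(small_periodic):
    ens = small_periodic(seed=2, n=8)
    ew0 = np.linalg.norm(ewald_dipolar_field(ens), axis=1)
    shifted = ens.positions + np.array([0.37, -0.11, 0.52]) * ens.box_length
    ens.positions = shifted % ens.box_length
    ew1 = np.linalg.norm(ewald_dipolar_field(ens), axis=1)
    assert np.allclose(ew0, ew1, rtol=1e-10)


def test_dipolar_energy_pair_consistency(material):
    """E_i = -mu0 mu_i . H_dip(i) for a pair, positive for side-by-side
    parallel moments, zero for an isolated particle."""
    ens = make_pair(material, 25e-9, [1, 0, 0], [[0, 0, 1], [0, 0, 1]])
    E = dipolar_energy(ens, 0)
    H = direct_dipolar_field(ens, 0, 0)
    assert math.isclose(E, float(-MU0 * ens.moment_vectors[0] @ H), rel_tol=1e-12)
    assert E > 0  # parallel side-by-side dipoles repel
    single = build_uniform_ensemble(1, 0.05, 17e-9, material, seed=0)
    single.boundary = "open"
    assert dipolar_energy(single, 0) == 0.0


def test_local_fields_single_particle_reduced_quantities(material, env, protocol):
    """Zero-concentration limit: H = H0, psi = 0, and the reduced field and
    barrier match hand-computed values (h = 0.1681, sigma = 15.90 for a
    17 nm particle at 293 K)."""
    ens = build_uniform_ensemble(1, 1e-4, 17e-9, material, seed=0)
    ens = initialize_moments(ens, [0, 0, 1])
    st = local_fields(ens, protocol, material, env)
    # the only dipolar contribution is the particle's own image lattice
    assert abs(st.H[0] - protocol.H0) < 0.02 * protocol.H0
    assert st.psi[0] < 1e-6
    assert st.h[0] == pytest.approx(0.16815, rel=2e-2)
    assert st.sigma[0] == pytest.approx(15.898, rel=1e-3)
    assert np.allclose(st.xi, 2 * st.h * st.sigma, rtol=1e-12)


def test_xi_identity_on_ensembles(small_periodic, material, env, protocol):
    for seed in range(3):
        ens = small_periodic(seed=seed, n=8)
        st = local_fields(ens, protocol, material, env)
        assert np.allclose(st.xi, 2.0 * st.h * st.sigma, rtol=1e-12)


def test_mean_local_field_grows_with_concentration(material, env, protocol):
    """Average |H_loc| increases with volume fraction (10 nm system)."""
    means = []
    for r_V in (0.02, 0.10, 0.24):
        vals = []
        for seed in range(4):
            ens = build_uniform_ensemble(128, r_V, 10e-9, material, seed)
            from slpsim import assign_easy_axes

            ens = assign_easy_axes(ens, "random", [0, 0, 1], seed)
            ens = initialize_moments(ens, [0, 0, 1])
            vals.append(local_fields(ens, protocol, material, env).H.mean())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_self_consistent_moments_fixed_point(material, protocol):
    """The moment relaxation loop reaches a configuration in which every
    moment already sits in the easy-axis minimum selected by its own
    local field (a fixed point), flipping only a minority of moments."""
    from slpsim import assign_easy_axes
    from slpsim.dipolar import self_consistent_moments

    ens = build_uniform_ensemble(100, 0.2, 10e-9, material, 1)
    ens = initialize_moments(assign_easy_axes(ens, "random", [0, 0, 1], 1), [0, 0, 1])
    out = self_consistent_moments(ens, protocol)
    H_ext = protocol.H0 * protocol.direction_array
    H_loc = ewald_dipolar_field(out) + H_ext
    sign = np.sign(np.einsum("ik,ik->i", H_loc, out.easy_axes))
    assert np.allclose(out.moment_dirs, sign[:, None] * out.easy_axes)
    # the field-aligned start is already near equilibrium: few flips
    n_flipped = int((np.einsum("ik,ik->i", out.moment_dirs, ens.moment_dirs) < 0).sum())
    assert n_flipped < ens.n // 2
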