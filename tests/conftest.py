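import math

import numpy as np
import pytest

from slpsim import (
    Ensemble,
    Environment,
    FieldProtocol,
    MaterialParams,
    assign_easy_axes,
    build_uniform_ensemble,
    initialize_moments,
)


@pytest.fixture
def material():
    return MaterialParams()


@pytest.fixture
def env():
    return Environment()


@pytest.fixture
def protocol():
    return FieldProtocol()


@pytest.fixture
def small_periodic(material):
    """Six-particle periodic fixture with random axes and axis-aligned
    moments; small enough for brute-force field oracles."""

    def factory(seed=1, n=6, r_V=0.08, d=10e-9):
        ens = build_uniform_ensemble(n, r_V, d, material, seed)
        ens = assign_easy_axes(ens, "random", [0, 0, 1], seed)
        return initialize_moments(ens, [0, 0, 1])

    return factory


def make_pair(material, separation, direction, moment_dirs, d=17e-9):
    """Open-boundary two-particle system with explicit geometry."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    positions = np.stack([np.zeros(3), separation * direction])
    dirs = np.asarray(moment_dirs, float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    return Ensemble(
        positions=positions,
        core_diameters=np.full(2, d),
        hydro_diameters=np.full(2, d),
        easy_axes=dirs.copy(),
        moment_dirs=dirs.copy(),
        box_length=10 * separation,
        boundary="open",
        r_V=2 * (math.pi / 6) * d**3 / (10 * separation) ** 3,
        material=material,
        seed=0,
    )


def grid_scan_extrema(psi, h, n_theta=200001, refine=False):
    """Independent dense-grid landscape oracle: locate the two minima and
    the lower in-plane maximum (the saddle) of sin^2(t) - 2h cos(t - psi)
    on [0, pi] by direct scanning, optionally polished by a three-point
    parabolic fit around each grid extremum."""
    t = np.linspace(0.0, math.pi, n_theta)
    e = np.sin(t) ** 2 - 2.0 * h * np.cos(t - psi)
    interior = np.arange(1, n_theta - 1)
    mins = interior[(e[interior] < e[interior - 1]) & (e[interior] < e[interior + 1])]
    maxs = interior[(e[interior] > e[interior - 1]) & (e[interior] > e[interior + 1])]

    def polish(i):
        if not refine or i == 0 or i == n_theta - 1:
            return t[i]
        dt = t[1] - t[0]
        denom = e[i - 1] - 2 * e[i] + e[i + 1]
        if denom == 0:
            return t[i]
        return t[i] + 0.5 * dt * (e[i - 1] - e[i + 1]) / denom

    minima = [polish(i) for i in mins]
    if e[0] < e[1]:
        minima.insert(0, 0.0)
    if e[-1] < e[-2]:
        minima.append(math.pi)
    assert len(minima) == 2 and len(maxs) == 1
    return minima[0], minima[1], polish(maxs[0])
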