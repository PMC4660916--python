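"""Construction of nanoparticle ensembles on lattice sites.

Particles occupy randomly selected sites of a cubic lattice inside a cubic
simulation box.  The default site set places particles on the vertices and
face centres of each unit cell (an fcc-type arrangement, 4 sites per
conventional cell); a strict body-centred set (vertex + body centre,
2 sites per cell) is available through ``site_set="bcc"``.

The box edge is chosen as L = (n V / r_V)^(1/3) so the achieved volume
fraction matches the request exactly for monodisperse particles; the number
of unit cells per edge is the smallest that provides at least ``n`` sites,
which maximizes the lattice spacing (and hence the minimum inter-particle
separation) at the requested dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .params import MaterialParams

# fractional site offsets within one conventional cubic cell
_SITE_OFFSETS = {
    # vertices + the three face centres owned by each cell
    "vertex_face": np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    ),
    # vertices + body centre
    "bcc": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
}

#: nearest-neighbour distance in units of the cell edge a
_MIN_SEPARATION = {"vertex_face": math.sqrt(0.5), "bcc": math.sqrt(3.0) / 2.0}


class PackingError(ValueError):
    """Requested volume fraction cannot be realized on the site lattice."""


@dataclass
class Ensemble:
    """A set of spherical single-domain particles in a cubic box.

    Attributes use SI units.  ``positions`` is (N, 3); ``easy_axes`` and
    ``moment_dirs`` are (N, 3) unit vectors; ``core_diameters`` and
    ``hydro_diameters`` are (N,).
    """

    positions: np.ndarray
    core_diameters: np.ndarray
    hydro_diameters: np.ndarray
    easy_axes: np.ndarray
    moment_dirs: np.ndarray
    box_length: float
    boundary: str  # "periodic" | "open"
    r_V: float
    material: MaterialParams
    seed: int
    r_V_loc: Optional[float] = None
    site_set: str = "vertex_face"

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def volumes(self) -> np.ndarray:
        """Core volumes (pi/6) d^3, m^3."""
        return (math.pi / 6.0) * self.core_diameters**3

    @property
    def hydro_volumes(self) -> np.ndarray:
        """Hydrodynamic volumes (pi/6) d_h^3, m^3."""
        return (math.pi / 6.0) * self.hydro_diameters**3

    @property
    def moments(self) -> np.ndarray:
        """Moment magnitudes mu = Ms * V, A m^2."""
        return self.material.Ms * self.volumes

    @property
    def moment_vectors(self) -> np.ndarray:
        """Full moment vectors mu_i * m_hat_i, (N, 3), A m^2."""
        return self.moments[:, None] * self.moment_dirs

    def achieved_volume_fraction(self) -> float:
        return float(self.volumes.sum() / self.box_length**3)

    def validate(self, atol: float = 1e-12) -> None:
        """Check the structural invariants; raise AssertionError on failure."""
        assert np.all(np.abs(np.linalg.norm(self.easy_axes, axis=1) - 1) < atol)
        assert np.all(np.abs(np.linalg.norm(self.moment_dirs, axis=1) - 1) < atol)
        assert np.all(self.hydro_diameters >= self.core_diameters - 1e-30)
        if self.boundary == "periodic":
            assert np.all(self.positions >= 0.0)
            assert np.all(self.positions < self.box_length)


def _lattice_sites(m: int, site_set: str) -> np.ndarray:
    """Fractional coordinates (in cell-edge units) of all sites of an
    m x m x m block of unit cells."""
    offs = _SITE_OFFSETS[site_set]
    cells = np.stack(
        np.meshgrid(np.arange(m), np.arange(m), np.arange(m), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    return (cells[:, None, :] + offs[None, :, :]).reshape(-1, 3)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent derived streams per stage, reproducible per master seed
    return np.random.default_rng([int(seed), int(stream)])


def _place(
    n: int, r_V: float, d: float, seed: int, site_set: str
) -> tuple[np.ndarray, float]:
    """Pick n random lattice sites; return positions (m) and box edge (m)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < r_V < 1.0:
        raise ValueError("volume fraction must lie in (0, 1)")
    if site_set not in _SITE_OFFSETS:
        raise ValueError(f"unknown site_set {site_set!r}")
    sites_per_cell = len(_SITE_OFFSETS[site_set])
    V = (math.pi / 6.0) * d**3
    L = (n * V / r_V) ** (1.0 / 3.0)
    # smallest cell count whose site total accommodates n particles
    m = max(1, math.ceil((n / sites_per_cell) ** (1.0 / 3.0)))
    while sites_per_cell * m**3 < n:
        m += 1
    a = L / m
    min_sep = _MIN_SEPARATION[site_set] * a
    if min_sep < d:
        # particles would overlap: the lattice cannot hold this fraction
        r_max = r_V * (min_sep / d) ** 3
        raise PackingError(
            f"volume fraction {r_V} infeasible for n={n}, d={d:.3g} m on the "
            f"{site_set} site set; maximum achievable is {r_max:.4g}"
        )
    sites = _lattice_sites(m, site_set) * a
    n_sites = sites.shape[0]
    if n == n_sites:
        chosen = np.arange(n_sites)  # full occupancy: seed-independent
    else:
        chosen = _rng(seed, 0).choice(n_sites, size=n, replace=False)
        chosen.sort()
    return sites[chosen], L


def build_uniform_ensemble(
    n: int,
    r_V: float,
    d: float,
    material: MaterialParams,
    seed: int,
    *,
    d_hydro: Optional[float] = None,
    site_set: str = "vertex_face",
) -> Ensemble:
    """Uniform random ensemble: n particles of core diameter d placed on
    random lattice sites of a periodic cubic box sized for volume fraction
    r_V.  Easy axes and moments start along +z; use :func:`assign_easy_axes`
    and :func:`initialize_moments` to configure them."""
    positions, L = _place(n, r_V, d, seed, site_set)
    z = np.tile([0.0, 0.0, 1.0], (n, 1))
    dh = d if d_hydro is None else float(d_hydro)
    if dh < d:
        raise ValueError("hydrodynamic diameter must be >= core diameter")
    return Ensemble(
        positions=positions,
        core_diameters=np.full(n, float(d)),
        hydro_diameters=np.full(n, dh),
        easy_axes=z.copy(),
        moment_dirs=z.copy(),
        box_length=L,
        boundary="periodic",
        r_V=float(r_V),
        material=material,
        seed=int(seed),
        site_set=site_set,
    )


def build_cluster(
    n_cluster: int,
    r_V_loc: float,
    d: float,
    material: MaterialParams,
    seed: int,
    *,
    r_V_global: Optional[float] = None,
    d_hydro: Optional[float] = None,
    site_set: str = "vertex_face",
) -> Ensemble:
    """Dense cluster: n_cluster particles on random sites of a compact
    lattice block whose volume sets the local fraction r_V_loc, embedded
    centrally in an otherwise empty periodic box.

    The box edge is chosen from ``r_V_global`` (default 0.1 when the local
    fraction exceeds it, else a dilute 3x block edge), so the cluster's
    periodic images stay well separated.
    """
    if n_cluster < 2:
        raise ValueError("a cluster needs at least 2 particles")
    positions, L_loc = _place(n_cluster, r_V_loc, d, seed, site_set)
    V = (math.pi / 6.0) * d**3
    if r_V_global is None:
        L = 3.0 * L_loc
    else:
        if not 0.0 < r_V_global < 1.0:
            raise ValueError("global fraction must lie in (0, 1)")
        # the box can never be smaller than the cluster block itself
        L = max(L_loc, (n_cluster * V / r_V_global) ** (1.0 / 3.0))
    shift = 0.5 * (L - L_loc)
    positions = positions + shift
    z = np.tile([0.0, 0.0, 1.0], (n_cluster, 1))
    dh = d if d_hydro is None else float(d_hydro)
    return Ensemble(
        positions=positions,
        core_diameters=np.full(n_cluster, float(d)),
        hydro_diameters=np.full(n_cluster, dh),
        easy_axes=z.copy(),
        moment_dirs=z.copy(),
        box_length=L,
        boundary="periodic",
        r_V=float(n_cluster * V / L**3),
        material=material,
        seed=int(seed),
        r_V_loc=float(r_V_loc),
        site_set=site_set,
    )


def assign_easy_axes(
    ensemble: Ensemble, mode: str, field_dir, seed: int
) -> Ensemble:
    """Return a copy with easy axes set: ``parallel`` aligns every axis with
    the field direction; ``random`` draws i.i.d. uniform directions on the
    unit sphere (deterministic per seed)."""
    field_dir = np.asarray(field_dir, dtype=float)
    field_dir = field_dir / np.linalg.norm(field_dir)
    n = ensemble.n
    if mode == "parallel":
        axes = np.tile(field_dir, (n, 1))
    elif mode == "random":
        g = _rng(seed, 1)
        v = g.normal(size=(n, 3))
        axes = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown axes mode {mode!r}")
    return replace(ensemble, easy_axes=axes, moment_dirs=ensemble.moment_dirs.copy())


def initialize_moments(
    ensemble: Ensemble, field_dir, policy: str = "axis_aligned"
) -> Ensemble:
    """Return a copy with moment directions set.

    ``axis_aligned`` puts each moment in the easy-axis minimum nearest the
    field (moment = ±axis with non-negative projection on the field);
    ``field_aligned`` points every moment along the field.
    """
    field_dir = np.asarray(field_dir, dtype=float)
    field_dir = field_dir / np.linalg.norm(field_dir)
    if policy == "axis_aligned":
        sign = np.where(ensemble.easy_axes @ field_dir < 0.0, -1.0, 1.0)
        moments = sign[:, None] * ensemble.easy_axes
    elif policy == "field_aligned":
        moments = np.tile(field_dir, (ensemble.n, 1))
    else:
        raise ValueError(f"unknown moment policy {policy!r}")
    return replace(ensemble, moment_dirs=moments)


def minimum_pair_distance(ensemble: Ensemble) -> float:
    """Smallest pair separation (minimum-image for periodic boxes), m."""
    r = ensemble.positions
    dr = r[:, None, :] - r[None, :, :]
    if ensemble.boundary == "periodic":
        L = ensemble.box_length
        dr -= L * np.round(dr / L)
    dist = np.linalg.norm(dr, axis=-1)
    np.fill_diagonal(dist, np.inf)
    return float(dist.min())
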