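"""Polymer conformations and their contact-space networks.

Three coarse-grained chromatin models supply explicit 3D conformations whose
contact topology can be compared against the parametric contact-space models:

* **freely rotating chain (FRC)** — unit bonds, fixed angle ``theta`` between
  successive bond vectors, uniform azimuthal rotation.  ``theta -> 0`` is a
  rod; large ``theta`` folds the chain back on itself and collapses it.
* **Lennard-Jones bead-spring chain** — harmonic springs between neighbours
  plus an attractive LJ pair potential with hard-core repulsion.
* **soft-LJ chain** — the LJ attraction with the repulsive core replaced by a
  finite overlap penalty ``V0 - eps``, softness set by ``eta1``.

Conformations are converted to `ConnectivityMatrix` networks by a distance
cutoff ``r_c`` (beads ``|i-j| >= 2`` within ``r_c`` are bonded; the backbone is
always bonded).  The cutoff is a free parameter of the analysis; the default
``r_c = 1.5 sigma`` (midway between bead contact at 1 and the attraction range
2.5) is exposed everywhere.

A reduced-scale Langevin integrator (velocity Verlet with friction and
thermal noise) equilibrates LJ / soft-LJ chains at test scale (L up to a few
hundred beads); it is not meant to reproduce full coil-globule phase diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .contact_models import ConnectivityMatrix

__all__ = [
    "PolymerConformation",
    "FRCParams",
    "EnergyParams",
    "LangevinParams",
    "generate_frc",
    "radius_of_gyration",
    "conformation_to_network",
    "spring_energy",
    "lj_energy",
    "soft_lj_energy",
    "langevin_evolve",
    "contact_probability_curve",
    "read_xyz",
    "write_xyz",
]

DEFAULT_CUTOFF_RADIUS = 1.5  # sigma units; see module docstring


@dataclass
class PolymerConformation:
    """Ordered 3D bead positions, bond lengths in units of sigma = 1."""

    coords: np.ndarray = field(repr=False)
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_beads, 3)")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)


@dataclass(frozen=True)
class FRCParams:
    """Freely rotating chain: ``theta`` in degrees, ``L`` beads."""

    theta: float
    L: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 180.0:
            raise ValueError("theta must lie in [0, 180) degrees")
        if self.L < 2:
            raise ValueError("need at least 2 beads")


@dataclass(frozen=True)
class EnergyParams:
    """Bead-spring energy parameters (reduced units, sigma = 1).

    ``V0``, ``eta1``, ``eta2`` and ``r_m`` only matter for the soft-LJ form:
    the overlap penalty is ``V0 - epsilon`` and ``eta1`` sets the softness
    (smaller = softer).
    """

    k: float = 100.0
    epsilon: float = 1.0
    sigma: float = 1.0
    cutoff: float = 2.5
    V0: float = 1.0e7
    eta1: float = 0.05
    eta2: float = 3.16
    r_m: float = 1.12

    def __post_init__(self) -> None:
        for name in ("k", "sigma", "cutoff", "V0", "eta1", "eta2", "r_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters: unit mass and friction, time step 0.01."""

    m: float = 1.0
    gamma_fric: float = 1.0
    kBT: float = 1.0
    dt: float = 0.01
    n_steps: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@njit(cache=True)
def _frc_chain(L, cos_t, sin_t, phis):  # pragma: no cover - numba
    coords = np.zeros((L, 3))
    # local frame: b = current bond direction, (n1, n2) orthonormal complement
    bx, by, bz = 0.0, 0.0, 1.0
    n1x, n1y, n1z = 1.0, 0.0, 0.0
    n2x, n2y, n2z = 0.0, 1.0, 0.0
    coords[1, 2] = 1.0
    for i in range(2, L):
        phi = phis[i - 2]
        cx = np.cos(phi)
        sx = np.sin(phi)
        # new bond at polar angle theta from b, azimuth phi in (n1, n2) plane
        nbx = cos_t * bx + sin_t * (cx * n1x + sx * n2x)
        nby = cos_t * by + sin_t * (cx * n1y + sx * n2y)
        nbz = cos_t * bz + sin_t * (cx * n1z + sx * n2z)
        norm = np.sqrt(nbx * nbx + nby * nby + nbz * nbz)
        nbx /= norm
        nby /= norm
        nbz /= norm
        coords[i, 0] = coords[i - 1, 0] + nbx
        coords[i, 1] = coords[i - 1, 1] + nby
        coords[i, 2] = coords[i - 1, 2] + nbz
        # rebuild frame around the new bond
        if abs(nbz) < 0.9:
            ax, ay, az = 0.0, 0.0, 1.0
        else:
            ax, ay, az = 1.0, 0.0, 0.0
        n1x = nby * az - nbz * ay
        n1y = nbz * ax - nbx * az
        n1z = nbx * ay - nby * ax
        norm = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
        n1x /= norm
        n1y /= norm
        n1z /= norm
        n2x = nby * n1z - nbz * n1y
        n2y = nbz * n1x - nbx * n1z
        n2z = nbx * n1y - nby * n1x
        bx, by, bz = nbx, nby, nbz
    return coords


def generate_frc(params: FRCParams, rng_seed: int) -> PolymerConformation:
    """Sample one freely rotating chain conformation.

    The first bond points along +z; every later bond makes the fixed angle
    ``theta`` with its predecessor, with azimuth uniform on ``[0, 2 pi)``.
    """
    rng = np.random.default_rng(rng_seed)
    theta = np.deg2rad(params.theta)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=max(params.L - 2, 0))
    coords = _frc_chain(params.L, np.cos(theta), np.sin(theta), phis)
    return PolymerConformation(coords, provenance="frc")


def radius_of_gyration(conf: PolymerConformation) -> float:
    """Root-mean-square distance of beads from their centroid."""
    if conf.n_beads < 2:
        raise ValueError("need at least 2 beads")
    centred = conf.coords - conf.coords.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


def end_to_end_sq(conf: PolymerConformation) -> float:
    d = conf.coords[-1] - conf.coords[0]
    return float(d @ d)


def conformation_to_network(
    conf: PolymerConformation,
    r_c: float = DEFAULT_CUTOFF_RADIUS,
    insulate_boundaries: bool = True,
) -> ConnectivityMatrix:
    """Contact network of a conformation: bond iff ``r_ij <= r_c``, backbone forced.

    With ``insulate_boundaries`` (default) intersegmental bonds touching the
    terminal beads are dropped, matching the contact-space convention that the
    target sites are insulated from the domain interior and reachable only by
    sliding.
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    n = conf.n_beads
    adj = np.zeros((n, n), dtype=np.uint8)
    tree = cKDTree(conf.coords)
    for i, j in tree.query_pairs(r_c):
        if abs(i - j) < 2:
            continue
        if insulate_boundaries and (min(i, j) == 0 or max(i, j) == n - 1):
            continue
        adj[i, j] = 1
        adj[j, i] = 1
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = 1
    adj[idx + 1, idx] = 1
    return ConnectivityMatrix(n - 1, adj)


# ---------------------------------------------------------------------------
# energies and Langevin dynamics
# ---------------------------------------------------------------------------


def spring_energy(r: float, params: EnergyParams) -> float:
    """Harmonic backbone spring ``k/2 (r - sigma)^2``."""
    if r <= 0:
        raise ValueError("r must be positive")
    return 0.5 * params.k * (r - params.sigma) ** 2


def lj_energy(r, params: EnergyParams):
    """Lennard-Jones pair energy, zero beyond the 2.5 sigma cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    x = params.sigma / r
    e = 4.0 * params.epsilon * (x**12 - x**6)
    out = np.where(r < params.cutoff * params.sigma, e, 0.0)
    return float(out) if out.ndim == 0 else out


def soft_lj_energy(r, params: EnergyParams):
    """Soft-core LJ: finite overlap penalty below ``r_m``, LJ up to cutoff.

    ``E(r < r_m) = V0 [1 - (r/r_m)^eta1]^eta2 - eps``; ``E(0) = V0 - eps``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    rm = params.r_m
    with np.errstate(divide="ignore", invalid="ignore"):
        soft = (
            params.V0 * (1.0 - (r / rm) ** params.eta1) ** params.eta2
            - params.epsilon
        )
        x = params.sigma / np.where(r > 0, r, 1.0)
        lj = 4.0 * params.epsilon * (x**12 - x**6)
    out = np.where(
        r < rm, soft, np.where(r < params.cutoff * params.sigma, lj, 0.0)
    )
    return float(out) if out.ndim == 0 else out


def _pair_forces(coords: np.ndarray, ep: EnergyParams, soft: bool) -> np.ndarray:
    """Forces from the pair potential (LJ or soft-LJ) over all bead pairs."""
    n = coords.shape[0]
    F = np.zeros_like(coords)
    if ep.epsilon == 0.0 and not soft:
        return F
    d = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((d**2).sum(axis=2))
    np.fill_diagonal(r, np.inf)
    cut = ep.cutoff * ep.sigma
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x6 = (ep.sigma / r) ** 6
        # -dE/dr for LJ: 24 eps (2 x^12 - x^6) / r
        mag = 24.0 * ep.epsilon * (2.0 * x6 * x6 - x6) / r
        if soft:
            xr = (r / ep.r_m) ** ep.eta1
            soft_mag = (
                ep.V0 * ep.eta2 * (1.0 - xr) ** (ep.eta2 - 1.0) * ep.eta1 * xr / r
            )
            mag = np.where(r < ep.r_m, soft_mag, mag)
        mag = np.where(r < cut, mag, 0.0)
    # F_i = sum_j mag_ij * (r_i - r_j)/r_ij
    with np.errstate(invalid="ignore"):
        unit = d / r[:, :, None]
    F = (mag[:, :, None] * unit).sum(axis=1)
    return F


def _spring_forces(coords: np.ndarray, ep: EnergyParams) -> np.ndarray:
    F = np.zeros_like(coords)
    d = np.diff(coords, axis=0)
    r = np.linalg.norm(d, axis=1)
    mag = -ep.k * (r - ep.sigma)  # -dE/dr
    fvec = mag[:, None] * d / r[:, None]
    F[1:] += fvec
    F[:-1] -= fvec
    return F


def langevin_evolve(
    conf: PolymerConformation,
    energy: EnergyParams,
    dyn: LangevinParams,
    potential: str = "lj",
) -> PolymerConformation:
    """Evolve a bead-spring chain by Langevin dynamics (velocity Verlet).

    ``potential`` selects "lj" or "soft_lj" for the non-bonded pairs.
    Deterministic given ``dyn.rng_seed``.  Aborts if forces overflow (hard-LJ
    bead overlap).
    """
    if potential not in ("lj", "soft_lj"):
        raise ValueError("potential must be 'lj' or 'soft_lj'")
    soft = potential == "soft_lj"
    rng = np.random.default_rng(dyn.rng_seed)
    x = conf.coords.copy()
    n = x.shape[0]
    v = np.zeros_like(x)
    dt, m, g = dyn.dt, dyn.m, dyn.gamma_fric
    noise_amp = np.sqrt(2.0 * g * dyn.kBT / dt)

    def total_force(pos):
        F = _spring_forces(pos, energy) + _pair_forces(pos, energy, soft)
        if not np.all(np.isfinite(F)) or np.abs(F).max() > 1e12:
            raise FloatingPointError(
                "force overflow (bead overlap with hard-core potential); "
                "reduce dt or soften the potential"
            )
        return F

    F = total_force(x)
    for _ in range(dyn.n_steps):
        noise = noise_amp * rng.standard_normal((n, 3)) if dyn.kBT > 0 else 0.0
        a = (F - g * v + noise) / m
        v_half = v + 0.5 * dt * a
        x = x + dt * v_half
        F = total_force(x)
        noise = noise_amp * rng.standard_normal((n, 3)) if dyn.kBT > 0 else 0.0
        v = v_half + 0.5 * dt * (F - g * v_half + noise) / m
    return PolymerConformation(x, provenance="soft_lj" if soft else "lj")


def contact_probability_curve(
    networks: list[ConnectivityMatrix],
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ``P_c(s)``: bond frequency per separation over an ensemble.

    Averages over interior bead pairs (both endpoints in ``1..L-1``) for
    ``s >= 2``, matching the eligible-pair set of the parametric models;
    ``P_c(1) = 1`` by backbone construction.  Returns ``(s, P_c(s))``.
    """
    if not networks:
        raise ValueError("need at least one network")
    L = networks[0].L
    if any(net.L != L for net in networks):
        raise ValueError("all networks must share the same L")
    s_vals = np.arange(1, L)
    pc = np.zeros(L - 1)
    pc[0] = 1.0
    acc = np.zeros((L + 1, L + 1), dtype=np.int64)
    for net in networks:
        acc += net.adj
    interior = acc[1:L, 1:L]
    m = interior.shape[0]
    for s in range(2, L):
        if s >= m:
            break
        diag = np.diagonal(interior, offset=s)
        pc[s - 1] = diag.sum() / (diag.size * len(networks))
    return s_vals, pc


# ---------------------------------------------------------------------------
# xyz I/O (standard "N / comment / element x y z" frames)
# ---------------------------------------------------------------------------


def write_xyz(conf: PolymerConformation, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{conf.n_beads}\n{comment}\n")
        for x, y, z in conf.coords:
            fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> PolymerConformation:
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()  # comment
        coords = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    return PolymerConformation(coords, provenance="external")
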