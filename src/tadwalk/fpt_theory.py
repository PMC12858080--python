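"""Exact mean first-passage times for the contact-space search process.

The searcher occupies one of ``L + 2`` states: polymer beads ``0..L`` (0 and L
absorbing) and a free bulk state ``f``.  Writing ``T_i`` for the mean time to
absorption starting from state ``i``, the backward equations form a linear
system ``A T = B``:

* absorbing rows:  ``T_0 = T_L = 0``
* bulk row:        ``T_f = tau_f + (1/(L+1)) sum_j T_j``  (uniform rebinding
  over all beads, including the targets)
* interior row i:  ``T_i = b_i + (1-p_off)/N_i sum_j C_ij T_j + p_off T_f``

where ``N_i`` is the degree of bead ``i`` and ``b_i`` the expected residence
time per step: ``tau`` when sliding and jumping cost the same, otherwise
``(1-p_off) (2 tau + (N_i - 2) t_jump)/N_i + p_off tau`` (two backbone moves at
cost ``tau``, the rest at ``t_jump``; the unbinding step itself costs ``tau``
before the ``tau_f`` excursion, which is charged on the bulk row).

Two solvers are exposed:

``solve_quenched``
    solves the system for one fixed (quenched) connectivity matrix.

``solve_annealed``
    models a network redrawn afresh at every walker step (fully dynamic
    polymer).  The per-step transition probability then equals its expectation
    ``E[C_ij / N_i]`` over the bond ensemble, evaluated *exactly* by
    conditioning on the moved-along bond and integrating over the
    Poisson-binomial distribution of the remaining degree:

        E[1/(a + K)] = int_0^1 u^(a-1) prod_k (1 - p_k (1 - u)) du,

    with ``K`` the sum of independent Bernoulli(p_k) bond indicators.  The
    integrand is a polynomial of degree ``<= L``, so Gauss-Legendre quadrature
    with ``(L + 5)//2 + 1`` nodes evaluates it exactly (up to rounding).

Printed asymptotics of the annealed uniform model are provided as
``low_pu_approx`` (leading order in ``p_u``, valid for ``p_u << 1/L^2``) and
``high_pu_approx`` (the ``p_u -> 1`` closed form; note it is an asymptote, not
exact at ``p_u = 1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_models import (
    ConnectivityMatrix,
    ContactModel,
    build_connectivity,
    probability_matrix,
)
from .walker_sim import SearchEstimate, WalkerParams

__all__ = [
    "FPTSolution",
    "build_fpt_system",
    "solve_quenched",
    "mean_quenched",
    "solve_annealed",
    "low_pu_approx",
    "high_pu_approx",
]

#: relative residual tolerance for accepting a linear solve
RESIDUAL_RTOL = 1e-10


@dataclass
class FPTSolution:
    """Per-site mean search times (units of tau).

    ``T[i]`` is the mean time to reach bead 0 or bead L starting from bead
    ``i``; ``T_free`` the mean time starting from the bulk state; ``T_mid``
    the value at the default start bead ``floor(L/2)``.
    """

    L: int
    T: np.ndarray = field(repr=False)
    T_free: float = 0.0

    @property
    def T_mid(self) -> float:
        return float(self.T[self.L // 2])


def _residence_vector(
    degrees: np.ndarray, params: WalkerParams
) -> np.ndarray:
    """Expected time consumed per step at each interior bead."""
    tau, tj, p_off = params.tau, params.t_jump, params.p_off
    deg = degrees.astype(float)
    if tj == tau:
        return np.full(deg.shape, tau)
    move = (2.0 * tau + (deg - 2.0) * tj) / deg
    return (1.0 - p_off) * move + p_off * tau


def build_fpt_system(
    C: ConnectivityMatrix, params: WalkerParams
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the dense ``(L+2) x (L+2)`` system for a fixed network."""
    C.validate()
    L = C.L
    n = L + 1
    f = n  # index of the bulk state
    A = np.zeros((n + 1, n + 1))
    B = np.zeros(n + 1)

    A[0, 0] = 1.0
    A[L, L] = 1.0

    A[f, f] = 1.0
    A[f, :n] -= 1.0 / n
    B[f] = params.tau_f

    deg = C.degrees
    interior = np.arange(1, L)
    W = C.adj[interior, :].astype(float) / deg[interior, None]
    A[1:L, :n] = -(1.0 - params.p_off) * W
    A[1:L, f] = -params.p_off
    A[np.arange(1, L), np.arange(1, L)] += 1.0
    B[1:L] = _residence_vector(deg[interior], params)
    return A, B


def _check_residual(A: np.ndarray, x: np.ndarray, B: np.ndarray) -> None:
    res = np.linalg.norm(A @ x - B)
    scale = max(np.linalg.norm(B), 1.0)
    if not np.isfinite(res) or res > RESIDUAL_RTOL * scale * 1e4:
        raise np.linalg.LinAlgError(
            f"first-passage system solved poorly (residual {res:.3e})"
        )


def solve_quenched(C: ConnectivityMatrix, params: WalkerParams) -> FPTSolution:
    """Exact mean search times on one fixed connectivity matrix."""
    A, B = build_fpt_system(C, params)
    x = np.linalg.solve(A, B)
    _check_residual(A, x, B)
    return FPTSolution(L=C.L, T=x[: C.L + 1], T_free=float(x[C.L + 1]))


def mean_quenched(
    model: ContactModel,
    L: int,
    params: WalkerParams,
    n_configs: int,
    rng_seed: int,
) -> SearchEstimate:
    """Average of the quenched midpoint search time over sampled networks."""
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    start = params.start if params.start is not None else L // 2
    times = np.empty(n_configs)
    for k in range(n_configs):
        C = build_connectivity(model, L, int(rng.integers(0, 2**31 - 1)))
        times[k] = solve_quenched(C, params).T[start]
    sem = float(times.std(ddof=1) / np.sqrt(n_configs)) if n_configs > 1 else 0.0
    return SearchEstimate(
        mean=float(times.mean()),
        sem=sem,
        n_walks=0,
        n_configs=n_configs,
        T_d=L * L * params.tau / 4.0,
    )


# ---------------------------------------------------------------------------
# annealed (fully dynamic) solver
# ---------------------------------------------------------------------------


def _annealed_transition(model: ContactModel, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact expected transition weights for a freshly redrawn network.

    Returns ``(W, Wb)`` where ``W[i, j] = E[C_ij / N_i]`` for interior beads
    ``i`` and all beads ``j`` (zero where no bond is possible) and
    ``Wb[i] = E[1/N_i]`` given a backbone move (used for residence times).
    Uses the Gauss-Legendre representation described in the module docstring;
    separations are grouped so the whole computation is two matrix products.
    """
    n = L + 1
    P = probability_matrix(model, L)  # intersegmental probabilities only

    # quadrature on [0, 1], exact for polynomials of degree <= L + 4
    n_q = (L + 5) // 2 + 1
    x, w = np.polynomial.legendre.leggauss(n_q)
    u = 0.5 * (x + 1.0)
    w = 0.5 * w

    # log prod_k (1 - p_ik (1 - u)) for each interior bead i, via the identity
    # elig(i) = {sep 2..i-1 to the left} + {sep 2..L-1-i to the right}
    # plus (if boundary_factor > 0) the two boundary pairs.
    interior = np.arange(1, L)
    s_all = np.arange(0, L + 1)
    p_s = np.zeros(L + 1)
    if L >= 2:
        s_in = s_all[2:]
        if model.kind == "uniform":
            p_s[2:] = model.p_u
        else:
            p_s[2:] = np.minimum(1.0, model.c * s_in.astype(float) ** -model.gamma)

    # g[s, q] = log(1 - p(s) (1 - u_q)); cumulative over s gives interior sums
    one_minus_u = 1.0 - u
    g = np.log1p(-np.outer(p_s, one_minus_u))  # (L+1, n_q)
    gcum = np.cumsum(g, axis=0)  # gcum[m] = sum_{s<=m} g[s]; g[0]=g[1]=0

    logF = np.zeros((L - 1, n_q))
    left = interior - 1  # max separation towards bead 1
    right = L - 1 - interior  # max separation towards bead L-1
    logF += np.where(left[:, None] >= 2, gcum[np.minimum(left, L)], 0.0)
    logF += np.where(right[:, None] >= 2, gcum[np.minimum(right, L)], 0.0)

    bf = model.boundary_factor
    if bf > 0.0:
        pb_left = bf * p_s[np.maximum(interior, 2)] * (interior >= 2)
        pb_right = bf * p_s[np.maximum(L - interior, 2)] * (L - interior >= 2)
        logF += np.log1p(-np.outer(pb_left, one_minus_u))
        logF += np.log1p(-np.outer(pb_right, one_minus_u))

    F = np.exp(logF)  # (L-1, n_q)

    # backbone weight: E[1/(2+K_i)] = int u F_i(u) du
    Wb = F @ (w * u)

    # intersegmental weight towards separation s:
    # E[C/N] = p(s) int u^2 F_i(u) / (1 - p(s)(1-u)) du
    M1 = F * (w * u * u)[None, :]  # (L-1, n_q)
    with np.errstate(divide="ignore", invalid="ignore"):
        M2 = p_s[None, :] / (1.0 - np.outer(one_minus_u, p_s))  # (n_q, L+1)
    M2[:, :2] = 0.0
    R = M1 @ M2  # R[i-1, s]

    W = np.zeros((L - 1, n + 1))  # columns: beads 0..L (bulk handled later)
    sep = np.abs(interior[:, None] - s_all[None, :])
    mask = (P[interior, :] > 0.0) & (sep >= 2)
    if bf > 0.0 and bf != 1.0:
        # boundary pairs have probability bf * p(s): recompute their weight
        M2b = np.zeros_like(M2)
        pb = bf * p_s
        with np.errstate(divide="ignore", invalid="ignore"):
            M2b = pb[None, :] / (1.0 - np.outer(one_minus_u, pb))
        M2b[:, :2] = 0.0
        Rb = M1 @ M2b
        boundary_col = np.zeros_like(mask)
        boundary_col[:, 0] = True
        boundary_col[:, L] = True
        W[:, : n][mask & ~boundary_col] = R[
            np.nonzero(mask & ~boundary_col)[0],
            sep[mask & ~boundary_col],
        ]
        W[:, : n][mask & boundary_col] = Rb[
            np.nonzero(mask & boundary_col)[0],
            sep[mask & boundary_col],
        ]
    else:
        rows, cols = np.nonzero(mask)
        W[rows, cols] = R[rows, sep[rows, cols]]

    # backbone moves
    W[np.arange(L - 1), interior - 1] += Wb
    W[np.arange(L - 1), interior + 1] += Wb
    return W, Wb


def solve_annealed(
    model: ContactModel, L: int, params: WalkerParams
) -> FPTSolution:
    """Exact mean search times on a fully dynamic (annealed) network.

    The connectivity is redrawn from the model at every step, so the
    transition kernel is the exact bond-ensemble expectation ``E[C_ij/N_i]``.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    n = L + 1
    f = n
    W, Wb = _annealed_transition(model, L)

    A = np.zeros((n + 1, n + 1))
    B = np.zeros(n + 1)
    A[0, 0] = 1.0
    A[L, L] = 1.0
    A[f, f] = 1.0
    A[f, :n] -= 1.0 / n
    B[f] = params.tau_f

    p_off = params.p_off
    A[1:L, : n + 1] = -(1.0 - p_off) * W
    A[1:L, f] = -p_off
    A[np.arange(1, L), np.arange(1, L)] += 1.0

    tau, tj = params.tau, params.t_jump
    if tj == tau:
        B[1:L] = tau
    else:
        # E[(2 tau + K t_jump)/(2 + K)] = t_jump - 2 (t_jump - tau) E[1/(2+K)]
        move = tj - 2.0 * (tj - tau) * Wb
        B[1:L] = (1.0 - p_off) * move + p_off * tau
    B[f] = params.tau_f

    x = np.linalg.solve(A, B)
    _check_residual(A, x, B)
    return FPTSolution(L=L, T=x[:n], T_free=float(x[f]))


# ---------------------------------------------------------------------------
# printed asymptotics of the annealed uniform model
# ---------------------------------------------------------------------------


def low_pu_approx(L: int, p_u: float) -> float:
    """Leading-order scaled search time ``T/T_d`` for ``p_u << 1/L^2``.

    Returns ``1 - (L^3 - 5 L^2 - 20 L + 48)/48 * p_u``.
    """
    if p_u * L * L > 0.1:
        warnings.warn(
            "low_pu_approx outside its validity regime (p_u * L^2 > 0.1)",
            stacklevel=2,
        )
    return 1.0 - (L**3 - 5 * L**2 - 20 * L + 48) / 48.0 * p_u


def high_pu_approx(L: int, p_u: float, tau: float = 1.0) -> float:
    """High-connectivity asymptote of the mean search time (units of tau).

    ``T = [2 + (L-3) p_u + (2 + (L-4) p_u)^2] / (2 p_u)``; an asymptote for
    ``p_u -> 1``, undefined at ``p_u = 0``.
    """
    if p_u == 0.0:
        raise ZeroDivisionError("high_pu_approx is undefined at p_u = 0")
    return (2.0 + (L - 3) * p_u + (2.0 + (L - 4) * p_u) ** 2) / (2.0 * p_u) * tau
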