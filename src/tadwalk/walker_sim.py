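"""Monte-Carlo simulation of the first-passage target search.

A protein starts at an interior bead of the contact network and, once per
step, either unbinds into the bulk (probability ``p_off``; costs the residence
time ``tau`` plus the bulk excursion ``tau_f``, after which it rebinds
uniformly over all ``L + 1`` beads, targets included) or moves to a uniformly
chosen bonded neighbour (cost ``tau`` for a backbone slide, ``t_jump`` for an
intersegmental hop).  The search ends when bead 0 or bead L is reached.

Networks may be *static* (quenched: one draw per trajectory ensemble) or
*dynamic*: every ``t_config_switch`` walker steps the intersegmental bonds are
redrawn from the model with no memory of the previous configuration.  The
dynamic kernel samples bond rows lazily — only the rows the walker actually
visits within a switch window are drawn, with symmetry enforced against rows
already drawn in the same window — which is statistically identical to
redrawing the full symmetric matrix.

The inner loops are numba-compiled; a pure-1D search at L=500 (~6e4 steps per
trajectory) runs at ~10^8 steps/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .contact_models import ConnectivityMatrix, ContactModel, build_connectivity, probability_matrix

__all__ = [
    "WalkerParams",
    "SearchEstimate",
    "simulate_first_passage",
    "ensemble_search_time",
]


@dataclass(frozen=True)
class WalkerParams:
    """Timescales and rates of the searching protein.

    All times are in units of the sliding step time ``tau``.  ``start=None``
    means the domain midpoint ``floor(L/2)``.  ``t_config_switch=None`` (or
    ``inf``) is a static network; ``1`` redraws the bonds at every step.
    """

    tau: float = 1.0
    t_jump: float = 1.0
    p_off: float = 0.0
    tau_f: float = 100.0
    start: int | None = None
    t_config_switch: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_off <= 1.0:
            raise ValueError("p_off must lie in [0, 1]")
        if self.tau <= 0 or self.t_jump <= 0 or self.tau_f <= 0:
            raise ValueError("tau, t_jump and tau_f must be positive")
        if self.t_config_switch is not None and not (
            math.isinf(self.t_config_switch) or self.t_config_switch >= 1
        ):
            raise ValueError("t_config_switch must be >= 1 step (or None/inf)")

    @property
    def dynamic(self) -> bool:
        return self.t_config_switch is not None and math.isfinite(self.t_config_switch)

    def resolve_start(self, L: int) -> int:
        start = L // 2 if self.start is None else self.start
        if not 1 <= start <= L - 1:
            raise ValueError("start bead must be interior (1..L-1)")
        return start


@dataclass(frozen=True)
class SearchEstimate:
    """Ensemble mean search time with its standard error.

    ``T_d = L^2 tau / 4`` is the pure-1D reference time from the midpoint.
    """

    mean: float
    sem: float
    n_walks: int
    n_configs: int
    T_d: float

    @property
    def scaled(self) -> float:
        return self.mean / self.T_d


@njit(cache=True)
def _walks_static(
    indptr, indices, L, tau, t_jump, p_off, tau_f, start, n_walks, seed
):  # pragma: no cover - numba
    np.random.seed(seed)
    out = np.empty(n_walks)
    for w in range(n_walks):
        i = start
        t = 0.0
        while True:
            if p_off > 0.0 and np.random.random() < p_off:
                t += tau + tau_f
                i = np.random.randint(0, L + 1)
                if i == 0 or i == L:
                    break
                continue
            lo = indptr[i]
            deg = indptr[i + 1] - lo
            j = indices[lo + np.random.randint(0, deg)]
            if j - i == 1 or i - j == 1:
                t += tau
            else:
                t += t_jump
            i = j
            if i == 0 or i == L:
                break
        out[w] = t
    return out


@njit(cache=True)
def _walks_dynamic(
    P, L, tau, t_jump, p_off, tau_f, start, switch_every, n_walks, seed
):  # pragma: no cover - numba
    """Walks on a network redrawn every `switch_every` steps.

    Rows of the symmetric bond matrix are sampled lazily per switch window;
    `row_epoch[i]` records the window in which row i was last drawn and
    `C` holds the drawn entries so that symmetry is preserved within a window.
    """
    np.random.seed(seed)
    n = L + 1
    C = np.zeros((n, n), dtype=np.uint8)
    row_epoch = np.full(n, -1, dtype=np.int64)
    nbr = np.empty(n, dtype=np.int64)
    out = np.empty(n_walks)
    epoch = 0
    for w in range(n_walks):
        i = start
        t = 0.0
        steps = 0
        epoch += 1
        while True:
            if steps % switch_every == 0 and steps > 0:
                epoch += 1
            steps += 1
            if p_off > 0.0 and np.random.random() < p_off:
                t += tau + tau_f
                i = np.random.randint(0, n)
                if i == 0 or i == L:
                    break
                continue
            if row_epoch[i] != epoch:
                # draw row i, honouring entries already drawn this window
                for k in range(n):
                    if k == i:
                        C[i, k] = 0
                    elif k - i == 1 or i - k == 1:
                        C[i, k] = 1
                    elif P[i, k] > 0.0:
                        if row_epoch[k] == epoch:
                            C[i, k] = C[k, i]
                        else:
                            val = 1 if np.random.random() < P[i, k] else 0
                            C[i, k] = val
                            C[k, i] = val
                    else:
                        C[i, k] = 0
                row_epoch[i] = epoch
            deg = 0
            for k in range(n):
                if C[i, k] == 1:
                    nbr[deg] = k
                    deg += 1
            j = nbr[np.random.randint(0, deg)]
            if j - i == 1 or i - j == 1:
                t += tau
            else:
                t += t_jump
            i = j
            if i == 0 or i == L:
                break
        out[w] = t
    return out


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_first_passage(
    C: ConnectivityMatrix,
    model: ContactModel,
    params: WalkerParams,
    rng_seed: int,
) -> float:
    """One trajectory's first-passage time on the given network.

    For dynamic parameters the model is used to redraw bonds; for static
    searches the model is ignored and the walk stays on ``C``.
    """
    L = C.L
    start = params.resolve_start(L)
    if params.dynamic:
        P = probability_matrix(model, L)
        times = _walks_dynamic(
            P,
            L,
            params.tau,
            params.t_jump,
            params.p_off,
            params.tau_f,
            start,
            int(params.t_config_switch),
            1,
            rng_seed,
        )
    else:
        indptr, indices = C.csr()
        times = _walks_static(
            indptr,
            indices,
            L,
            params.tau,
            params.t_jump,
            params.p_off,
            params.tau_f,
            start,
            1,
            rng_seed,
        )
    return float(times[0])


def ensemble_search_time(
    model: ContactModel,
    L: int,
    params: WalkerParams,
    n_configs: int,
    n_walks: int,
    rng_seed: int,
    C: ConnectivityMatrix | None = None,
) -> SearchEstimate:
    """Mean first-passage time over ``n_configs`` networks x ``n_walks`` walks.

    For static searches each configuration is a fresh draw from the model
    (or the fixed ``C`` if given, with ``n_configs`` ignored); for dynamic
    searches the configuration evolves within each trajectory and
    ``n_configs`` merely splits the walk budget into independent kernel runs.
    """
    if n_configs < 1 or n_walks < 1:
        raise ValueError("n_configs and n_walks must be >= 1")
    start = params.resolve_start(L)
    rng = np.random.default_rng(rng_seed)
    all_times = []
    if params.dynamic:
        P = probability_matrix(model, L)
        for _ in range(n_configs):
            all_times.append(
                _walks_dynamic(
                    P,
                    L,
                    params.tau,
                    params.t_jump,
                    params.p_off,
                    params.tau_f,
                    start,
                    int(params.t_config_switch),
                    n_walks,
                    _subseed(rng),
                )
            )
    else:
        for _ in range(n_configs):
            net = C if C is not None else build_connectivity(model, L, _subseed(rng))
            indptr, indices = net.csr()
            all_times.append(
                _walks_static(
                    indptr,
                    indices,
                    L,
                    params.tau,
                    params.t_jump,
                    params.p_off,
                    params.tau_f,
                    start,
                    n_walks,
                    _subseed(rng),
                )
            )
    times = np.concatenate(all_times)
    sem = float(times.std(ddof=1) / np.sqrt(times.size)) if times.size > 1 else 0.0
    return SearchEstimate(
        mean=float(times.mean()),
        sem=sem,
        n_walks=n_walks,
        n_configs=n_configs,
        T_d=L * L * params.tau / 4.0,
    )
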