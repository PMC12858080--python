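"""Contact-probability models and binary connectivity matrices.

A polymer domain of ``L + 1`` beads (indexed ``0..L``, targets at the two
boundary beads ``0`` and ``L``) is represented in *contact space* by a
symmetric binary matrix ``C``.  Backbone bonds ``C[i, i+1] = 1`` are always
present; every other pair may carry an intersegmental bond drawn as an
independent Bernoulli variable whose probability depends only on the genomic
separation ``s = |i - j|``:

* uniform model:    ``P_c(s) = p_u``            for ``s >= 2``
* power-law model:  ``P_c(s) = min(1, c s^-gamma)`` for ``s >= 2``

By default the boundary beads are fully insulated — intersegmental bonds are
drawn only among interior beads ``1..L-1`` — mirroring the insulation of TAD
boundary sites from the domain interior.  ``boundary_factor`` in ``(0, 1]``
relaxes this by multiplying the contact probability of any pair touching a
boundary bead.

Randomness contract: each sampling operation takes an integer seed and uses a
fresh ``numpy.random.default_rng(seed)`` (PCG64).  A single uniform variate is
drawn for every ordered bead pair via ``rng.random((L+1, L+1))`` (row-major);
the strict upper triangle decides the edges.  Two calls with the same model,
``L`` and seed therefore produce identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactModel",
    "ConnectivityMatrix",
    "BondCount",
    "contact_probability",
    "probability_matrix",
    "build_connectivity",
    "reshuffle_connectivity",
    "count_bonds",
    "write_edgelist",
    "read_edgelist",
]


@dataclass(frozen=True)
class ContactModel:
    """Parametric contact-probability law.

    Parameters
    ----------
    kind : {"uniform", "powerlaw"}
        Functional form of ``P_c(s)`` for separations ``s >= 2``.
    p_u : float
        Uniform per-pair contact probability (uniform model only).
    c : float
        Power-law prefactor (power-law model only).
    gamma : float
        Power-law decay exponent ``gamma >= 0``; smaller values mean more
        long-range contacts, i.e. a more compact domain.
    boundary_factor : float
        Multiplier in ``[0, 1]`` applied to contact probabilities of pairs
        touching bead 0 or bead L.  The default 0 is full insulation.
    """

    kind: str
    p_u: float = 0.0
    c: float = 0.0
    gamma: float = 0.0
    boundary_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "powerlaw"):
            raise ValueError(f"unknown contact model kind: {self.kind!r}")
        if self.kind == "uniform" and not 0.0 <= self.p_u <= 1.0:
            raise ValueError("p_u must lie in [0, 1]")
        if self.kind == "powerlaw":
            if self.c <= 0.0:
                raise ValueError("power-law prefactor c must be positive")
            if self.gamma < 0.0:
                raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.boundary_factor <= 1.0:
            raise ValueError("boundary_factor must lie in [0, 1]")

    @classmethod
    def uniform(cls, p_u: float, boundary_factor: float = 0.0) -> "ContactModel":
        return cls(kind="uniform", p_u=p_u, boundary_factor=boundary_factor)

    @classmethod
    def powerlaw(
        cls, c: float, gamma: float, boundary_factor: float = 0.0
    ) -> "ContactModel":
        return cls(kind="powerlaw", c=c, gamma=gamma, boundary_factor=boundary_factor)


def contact_probability(model: ContactModel, s):
    """Contact probability at genomic separation ``s`` (beads).

    ``s = 1`` is a backbone bond and returns 1; larger separations follow the
    model law, capped at 1.  ``s`` may be a scalar or an integer array.
    """
    s_arr = np.asarray(s)
    if not np.issubdtype(s_arr.dtype, np.integer) and not np.all(
        s_arr == np.floor(s_arr)
    ):
        raise ValueError("separation s must be integer")
    if np.any(s_arr < 1):
        raise ValueError("separation s must be >= 1")
    if model.kind == "uniform":
        p = np.full(s_arr.shape, model.p_u, dtype=float)
    else:
        p = np.minimum(1.0, model.c * np.asarray(s_arr, dtype=float) ** -model.gamma)
    p = np.where(s_arr == 1, 1.0, p)
    if np.isscalar(s) or s_arr.ndim == 0:
        return float(p)
    return p


def probability_matrix(model: ContactModel, L: int) -> np.ndarray:
    """Dense ``(L+1, L+1)`` matrix of intersegmental bond probabilities.

    Entries at ``|i - j| < 2`` are zero (backbone bonds are deterministic and
    handled separately); pairs touching bead 0 or L are scaled by
    ``boundary_factor``.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    n = L + 1
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore"):
        if model.kind == "uniform":
            P = np.full((n, n), model.p_u, dtype=float)
        else:
            P = np.minimum(
                1.0, model.c * np.maximum(s, 1).astype(float) ** -model.gamma
            )
    P[s < 2] = 0.0
    P[0, :] *= model.boundary_factor
    P[:, 0] *= model.boundary_factor
    P[L, :] *= model.boundary_factor
    P[:, L] *= model.boundary_factor
    return P


@dataclass
class ConnectivityMatrix:
    """One realisation of a polymer topology in contact space.

    ``adj`` is a dense symmetric uint8 adjacency over beads ``0..L`` with zero
    diagonal and the backbone super-diagonal always set.
    """

    L: int
    adj: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = self.L + 1
        if self.adj.shape != (n, n):
            raise ValueError("adjacency shape does not match L")

    def validate(self) -> None:
        """Assert all structural invariants (symmetry, backbone, binarity)."""
        a = self.adj
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency not symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency has nonzero diagonal")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency not binary")
        if not np.all(np.diag(a, k=1) == 1):
            raise ValueError("backbone bond missing")

    @property
    def degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(np.int64)

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) of the adjacency in CSR layout."""
        import scipy.sparse as sp

        m = sp.csr_matrix(self.adj)
        return m.indptr.astype(np.int64), m.indices.astype(np.int64)

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.L, self.adj.copy())


@dataclass(frozen=True)
class BondCount:
    """Number of non-neighbouring (intersegmental) bonds.

    ``N_b_max`` is the exact count of pairs with ``|i-j| >= 2`` among
    ``n = L+1`` beads: ``C(n, 2) - (n - 1)``.
    """

    N_b: int
    N_b_max: int


def _sample_adjacency(model: ContactModel, L: int, rng: np.random.Generator) -> np.ndarray:
    n = L + 1
    P = probability_matrix(model, L)
    U = rng.random((n, n))
    A = np.triu((U < P).astype(np.uint8), 2)
    A = A | A.T
    idx = np.arange(n - 1)
    A[idx, idx + 1] = 1
    A[idx + 1, idx] = 1
    return A


def build_connectivity(model: ContactModel, L: int, rng_seed: int) -> ConnectivityMatrix:
    """Draw one connectivity matrix: backbone plus Bernoulli intersegmental bonds."""
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(rng_seed)
    return ConnectivityMatrix(L, _sample_adjacency(model, L, rng))


def reshuffle_connectivity(
    C: ConnectivityMatrix, model: ContactModel, rng_seed: int
) -> ConnectivityMatrix:
    """Redraw all intersegmental bonds with no memory of the previous draw.

    The backbone is untouched; statistically this is identical to building a
    fresh matrix from the model.
    """
    rng = np.random.default_rng(rng_seed)
    return ConnectivityMatrix(C.L, _sample_adjacency(model, C.L, rng))


def count_bonds(C: ConnectivityMatrix) -> BondCount:
    """Count intersegmental bonds (unordered pairs with ``|i-j| >= 2``)."""
    n = C.L + 1
    upper = np.triu(C.adj, 2)
    n_b = int(upper.sum())
    n_b_max = n * (n - 1) // 2 - (n - 1)
    return BondCount(N_b=n_b, N_b_max=n_b_max)


def write_edgelist(C: ConnectivityMatrix, path) -> None:
    """Write edges as TSV ``i\tj`` (0-based, i < j) with a ``# L=<int>`` header."""
    ii, jj = np.nonzero(np.triu(C.adj, 1))
    with open(path, "w") as fh:
        fh.write(f"# L={C.L}\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\n")


def read_edgelist(path) -> ConnectivityMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# L="):
            raise ValueError("edge list must start with '# L=<int>' header")
        L = int(header.split("=", 1)[1])
        n = L + 1
        adj = np.zeros((n, n), dtype=np.uint8)
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i_s, j_s = line.split("\t")
            i, j = int(i_s), int(j_s)
            adj[i, j] = 1
            adj[j, i] = 1
    C = ConnectivityMatrix(L, adj)
    C.validate()
    return C
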