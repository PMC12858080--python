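"""Hi-C contact maps, TAD intervals, power-law fits and search-time scaling.

Inputs are a normalised (e.g. KR-balanced) contact-frequency matrix at 1-kb
resolution — dense TSV or COO triplet text — and a TAD interval list (BED3,
0-based half-open, bp).  Two routes connect the data to search kinetics:

* **Method 1** — per TAD, average the contact probability over all intra-TAD
  bin pairs at each separation ``s`` and fit ``P_c(s) = c s^-gamma`` by least
  squares on log-log axes over ``s in [10, L_kb - 100]``; the fitted ``(c,
  gamma)`` parameterise a power-law contact model for the solver.
* **Method 2** — draw Bernoulli networks directly from the scaled contact
  probabilities ``P_ij`` (backbone forced) and measure search times on them.

``fit_scaling_exponent`` extracts the exponent ``nu`` of the search-time /
domain-length scaling ``<T> ~ L^nu`` (``nu = 2`` is pure 1D diffusion,
``nu ~ 1`` near-ballistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from warnings import warn

import numpy as np
import pandas as pd

from .contact_models import ConnectivityMatrix

__all__ = [
    "HiCContactMap",
    "TADRecord",
    "PowerLawFit",
    "ScalingFit",
    "probability_scale",
    "intra_tad_contact_curve",
    "fit_power_law",
    "build_hic_network",
    "fit_scaling_exponent",
    "read_tads_bed",
]

DEFAULT_RESOLUTION = 1000  # bp per bin


@dataclass
class HiCContactMap:
    """Symmetric non-negative contact matrix over fixed-size genomic bins.

    ``normalisation`` is ``"raw"`` for balanced contact frequencies and
    ``"probability"`` once entries are contact probabilities in ``[0, 1]``
    (after `probability_scale`, or by construction for synthetic maps).
    """

    values: np.ndarray = field(repr=False)
    resolution: int = DEFAULT_RESOLUTION
    normalisation: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact map must be square")
        if np.any(self.values < 0):
            raise ValueError("contact values must be non-negative")
        if self.normalisation not in ("raw", "probability"):
            raise ValueError("normalisation must be 'raw' or 'probability'")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def scaled(self) -> bool:
        return self.normalisation == "probability"

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dense_tsv(cls, path, resolution: int = DEFAULT_RESOLUTION) -> "HiCContactMap":
        values = np.loadtxt(path, delimiter="\t")
        return cls(values=values, resolution=resolution)

    @classmethod
    def from_coo(
        cls, path, n_bins: int | None = None, resolution: int = DEFAULT_RESOLUTION
    ) -> "HiCContactMap":
        """Read triplet text ``bin_i  bin_j  value`` (0-based, whitespace/tab)."""
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["i", "j", "value"],
            dtype={"i": int, "j": int, "value": float},
        )
        if n_bins is None:
            n_bins = int(max(df["i"].max(), df["j"].max())) + 1
        values = np.zeros((n_bins, n_bins))
        values[df["i"], df["j"]] = df["value"]
        values[df["j"], df["i"]] = df["value"]
        return cls(values=values, resolution=resolution)

    def to_dense_tsv(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.8g")


@dataclass(frozen=True)
class TADRecord:
    """One TAD interval: 0-based half-open bp coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TAD end must exceed start")

    def n_bins(self, resolution: int = DEFAULT_RESOLUTION) -> int:
        return (self.end - self.start) // resolution

    @property
    def L_kb(self) -> int:
        return self.n_bins(DEFAULT_RESOLUTION)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law ``P_c(s) = c s^-gamma`` on log-log axes."""

    c: float
    gamma: float
    fit_range: tuple[float, float]
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ScalingFit:
    """Exponent of the search-time scaling ``<T> ~ L^nu``."""

    nu: float
    prefactor: float
    r_squared: float
    n_points: int


def read_tads_bed(path) -> list[TADRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    return [TADRecord(r.chrom, r.start, r.end) for r in df.itertuples()]


def probability_scale(hic: HiCContactMap) -> HiCContactMap:
    """Divide by the per-chromosome maximum off-diagonal contact frequency.

    After scaling all off-diagonal entries lie in ``[0, 1]`` with maximum
    exactly 1.  Idempotent.  Raises on an all-zero map.
    """
    off = hic.values.copy()
    np.fill_diagonal(off, 0.0)
    max_off = off.max()
    if max_off <= 0.0:
        raise ValueError("contact map has no positive off-diagonal entry")
    return replace(hic, values=hic.values / max_off, normalisation="probability")


def _tad_bins(hic: HiCContactMap, tad: TADRecord) -> tuple[int, int]:
    if tad.start % hic.resolution or tad.end % hic.resolution:
        warn(
            f"TAD {tad.chrom}:{tad.start}-{tad.end} not aligned to "
            f"{hic.resolution} bp bins; truncating",
            stacklevel=3,
        )
    b0 = tad.start // hic.resolution
    b1 = tad.end // hic.resolution
    if b0 < 0 or b1 > hic.n_bins or b1 - b0 < 2:
        raise ValueError("TAD outside contact map extent (or shorter than 2 bins)")
    return b0, b1


def intra_tad_contact_curve(
    hic: HiCContactMap, tad: TADRecord
) -> tuple[np.ndarray, np.ndarray]:
    """Mean contact value per genomic separation over all intra-TAD pairs.

    Returns ``(s, P_c(s))`` with ``s`` in bins (= kb at 1-kb resolution),
    ``s = 1 .. n_bins - 1``.
    """
    b0, b1 = _tad_bins(hic, tad)
    sub = hic.values[b0:b1, b0:b1]
    nb = sub.shape[0]
    s = np.arange(1, nb)
    pc = np.array([np.diagonal(sub, offset=k).mean() for k in s])
    return s, pc


def fit_power_law(
    s: np.ndarray,
    pc: np.ndarray,
    s_min: float = 10.0,
    s_max: float | None = None,
) -> PowerLawFit:
    """Fit ``log P = log c - gamma log s`` by ordinary least squares.

    ``s_max`` defaults to ``L_kb - 100`` where ``L_kb = len(s) + 1`` is the
    domain length in bins.  Non-positive ``P`` values in range are dropped
    with a warning; fewer than 4 usable points is an error.
    """
    s = np.asarray(s, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if s_max is None:
        s_max = (len(s) + 1) - 100.0
    if s_max <= s_min:
        raise ValueError(
            f"empty fit range [{s_min}, {s_max}]: domain too short for the "
            "default range; pass s_max explicitly"
        )
    in_range = (s >= s_min) & (s <= s_max)
    positive = pc > 0
    if np.any(in_range & ~positive):
        warn("non-positive contact values excluded from log-log fit", stacklevel=2)
    keep = in_range & positive
    if keep.sum() < 4:
        raise ValueError("fewer than 4 usable points in fit range")
    x = np.log(s[keep])
    y = np.log(pc[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        c=float(np.exp(intercept)),
        gamma=float(-slope),
        fit_range=(float(s_min), float(s_max)),
        r_squared=float(r2),
        n_points=int(keep.sum()),
    )


def build_hic_network(
    hic: HiCContactMap,
    tad: TADRecord,
    rng_seed: int,
    insulate_boundaries: bool = True,
) -> ConnectivityMatrix:
    """Bernoulli network drawn from intra-TAD contact probabilities.

    Each pair ``|i-j| >= 2`` gets a bond with probability ``P_ij``; the
    backbone is forced.  Requires a probability-scaled map.  By default the
    terminal (target) bins are insulated — no intersegmental bonds touch them
    — matching the contact-space search model.
    """
    if not hic.scaled:
        raise ValueError("map must be probability-scaled (see probability_scale)")
    b0, b1 = _tad_bins(hic, tad)
    P = np.minimum(hic.values[b0:b1, b0:b1], 1.0).copy()
    n = P.shape[0]
    if insulate_boundaries:
        P[0, :] = 0.0
        P[:, 0] = 0.0
        P[n - 1, :] = 0.0
        P[:, n - 1] = 0.0
    rng = np.random.default_rng(rng_seed)
    U = rng.random((n, n))
    adj = np.triu((U < P).astype(np.uint8), 2)
    adj = adj | adj.T
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = 1
    adj[idx + 1, idx] = 1
    return ConnectivityMatrix(n - 1, adj)


def fit_scaling_exponent(L_values, T_values) -> ScalingFit:
    """Log-log least-squares slope of mean search time versus domain length."""
    L_arr = np.asarray(L_values, dtype=float)
    T_arr = np.asarray(T_values, dtype=float)
    if L_arr.size != T_arr.size or L_arr.size < 4:
        raise ValueError("need at least 4 (L, T) pairs")
    if np.any(T_arr <= 0) or np.any(L_arr <= 0):
        raise ValueError("L and T must be positive")
    x = np.log(L_arr)
    y = np.log(T_arr)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return ScalingFit(
        nu=float(slope),
        prefactor=float(np.exp(intercept)),
        r_squared=float(r2),
        n_points=int(L_arr.size),
    )
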