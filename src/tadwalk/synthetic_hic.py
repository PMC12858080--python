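"""Synthetic Hi-C contact maps with known ground truth.

Generates a probability-valued contact map over a mock chromosome: intra-TAD
pairs follow ``P_ij = c_tad |i-j|^-gamma_tad``, all other pairs a background
law, each multiplied by lognormal noise (median-preserving, log-sd
``sigma_log``) and capped at 1.  The accompanying TAD list makes the whole
Hi-C pipeline (curve extraction, power-law fitting, Bernoulli networks)
testable without any download.

Defaults mirror the experimentally reported genome averages: TAD parameters
``(c, gamma) = (0.0214, 0.71)`` and a background at the chromosome-wide
exponent ``gamma = 1.08`` with the same prefactor.  Noise ``sigma_log = 0.2``
gives visually realistic scatter on log-log contact curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_tads import DEFAULT_RESOLUTION, HiCContactMap, TADRecord

__all__ = ["SyntheticMapSpec", "generate_map"]

TAD_C_DEFAULT = 0.0214
TAD_GAMMA_DEFAULT = 0.71
BACKGROUND_C_DEFAULT = 0.0214
BACKGROUND_GAMMA_DEFAULT = 1.08


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Ground truth for one synthetic chromosome.

    ``tads`` are (start_bp, end_bp) intervals; ``tad_params`` a matching list
    of (c, gamma) per TAD (or None for the defaults everywhere).
    """

    n_bins: int
    tads: tuple[tuple[int, int], ...]
    tad_params: tuple[tuple[float, float], ...] | None = None
    background: tuple[float, float] = (BACKGROUND_C_DEFAULT, BACKGROUND_GAMMA_DEFAULT)
    sigma_log: float = 0.2
    resolution: int = DEFAULT_RESOLUTION
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        prev_end = 0
        for start, end in self.tads:
            if start < prev_end:
                raise ValueError("TADs must be non-overlapping and sorted")
            if end <= start:
                raise ValueError("TAD end must exceed start")
            if end > self.n_bins * self.resolution:
                raise ValueError("TAD outside chromosome extent")
            prev_end = end
        if self.tad_params is not None and len(self.tad_params) != len(self.tads):
            raise ValueError("tad_params must match tads in length")

    def params_for(self, k: int) -> tuple[float, float]:
        if self.tad_params is None:
            return (TAD_C_DEFAULT, TAD_GAMMA_DEFAULT)
        return self.tad_params[k]


def generate_map(
    spec: SyntheticMapSpec, rng_seed: int
) -> tuple[HiCContactMap, list[TADRecord]]:
    """Build the probability map and TAD list for a spec; deterministic per seed.

    The returned map is flagged ``probability`` (its entries are probabilities
    by construction; the maximum off-diagonal value is generally below 1, so
    `probability_scale` would rescale — apply it only when emulating the
    raw-map normalisation step).
    """
    n = spec.n_bins
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :]).astype(float)
    s_safe = np.maximum(s, 1.0)

    c_bg, g_bg = spec.background
    P = c_bg * s_safe**-g_bg

    tads = []
    for k, (start, end) in enumerate(spec.tads):
        b0 = start // spec.resolution
        b1 = end // spec.resolution
        c_t, g_t = spec.params_for(k)
        block = slice(b0, b1)
        P[block, block] = c_t * s_safe[block, block] ** -g_t
        tads.append(TADRecord(spec.chrom, start, end))

    if spec.sigma_log > 0:
        rng = np.random.default_rng(rng_seed)
        noise = np.exp(spec.sigma_log * rng.standard_normal((n, n)))
        noise = np.triu(noise, 1)
        noise = noise + noise.T  # symmetric multiplicative noise
        P = P * np.where(noise > 0, noise, 1.0)

    np.fill_diagonal(P, 1.0)
    P = np.minimum(P, 1.0)
    P = np.triu(P, 0)
    P = P + np.triu(P, 1).T

    hic = HiCContactMap(
        values=P, resolution=spec.resolution, normalisation="probability"
    )
    return hic, tads
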