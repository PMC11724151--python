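"""Seed dispersal: truncated negative-exponential kernel + recruitment.

Offspring leave their natal cell following an isotropic negative
exponential kernel, p(r) ∝ exp(-r / α), where the decay scale α is half
the species' mean dispersal distance (the mean of a 2-D negative
exponential displacement is 2α).  The kernel is discretised at cell
centres, truncated at the species' maximum dispersal distance, and
renormalised to sum to one, so truncation itself never loses seeds —
only the absorbing grid boundary does.

Recruitment converts dispersed seed mass into integer individuals:
either a per-cell Poisson draw (demographic stochasticity) or a
deterministic floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .errors import ValueParseError


@dataclass(frozen=True)
class DispersalKernel:
    """Normalised square dispersal weight window.

    ``weights`` has side 2*radius + 1 and sums to one; the central entry
    is the probability that a seed stays in its natal cell.
    """

    weights: np.ndarray
    radius: int
    alpha: float  # decay scale = mean dispersal distance / 2, in cells


def build_kernel(
    mean_dispersal_dist: float, max_dispersal_dist: int
) -> DispersalKernel:
    """Build the truncated, normalised negative-exponential kernel.

    Weights are exp(-d/α) at Euclidean cell-centre distance d for every
    offset with d <= max_dispersal_dist, zero beyond.  A mean distance
    far below one cell underflows every off-centre weight, leaving a
    kernel that retains virtually all seeds at the origin.
    """
    if max_dispersal_dist < 1:
        raise ValueParseError("max_dispersal_dist must be at least 1")
    if mean_dispersal_dist <= 0:
        raise ValueParseError("mean_dispersal_dist must be > 0")

    radius = int(max_dispersal_dist)
    alpha = mean_dispersal_dist / 2.0
    offsets = np.arange(-radius, radius + 1)
    dist = np.hypot(offsets[:, None], offsets[None, :])
    with np.errstate(over="ignore", under="ignore"):
        weights = np.exp(-dist / alpha)
    weights[dist > max_dispersal_dist] = 0.0
    total = weights.sum()
    if total == 0.0:  # extreme underflow: all seeds stay home
        weights[radius, radius] = 1.0
        total = 1.0
    return DispersalKernel(weights=weights / total, radius=radius, alpha=alpha)


def disperse(seeds: np.ndarray, kernel: DispersalKernel) -> np.ndarray:
    """Redistribute seed mass over the grid with absorbing edges.

    Direct 2-D convolution with zero-padding: mass scattered beyond the
    grid boundary is lost.  For sources farther than the kernel radius
    from every edge, total arrivals equal total seeds.
    """
    seeds = np.asarray(seeds, dtype=float)
    if np.any(seeds < 0):
        raise ValueParseError("seed field must be non-negative")
    return convolve2d(seeds, kernel.weights, mode="same", boundary="fill", fillvalue=0.0)


def recruit(
    arrivals: np.ndarray,
    stochastic: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Turn dispersed seed mass into integer recruits.

    Stochastic mode draws independent Poisson counts with λ equal to the
    local arrival mass (cells consumed in row-major order from ``rng``);
    deterministic mode simply rounds down.
    """
    arrivals = np.asarray(arrivals, dtype=float)
    if np.any(arrivals < 0):
        raise ValueParseError("arrival field must be non-negative")
    if stochastic:
        if rng is None:
            raise ValueParseError("stochastic recruitment needs a random generator")
        return rng.poisson(arrivals).astype(np.int64)
    return np.floor(arrivals).astype(np.int64)
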