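"""Local population dynamics: one within-cell update per timestep.

Each step splits a population of size N into *survivors* (adults that
live through the step) and *seeds* (pre-dispersal offspring).  Seeds are
kept real-valued here; they only become integer individuals at
recruitment, after dispersal.  Survivors are floored so abundance stays
integral throughout.

Beverton–Holt with background mortality m and suitability-scaled
carrying capacity K_h:

    N' = N*r / (1 + r*N / (K_h * r*m/(r-m))) + N - N*m
       = N*r / (1 + N*(r-m)/(K_h*m))        + N*(1-m)

The density-dependent denominator is calibrated so the closed-cell map
has its unique positive fixed point exactly at N = K_h: at that size the
recruitment term equals K_h*m, exactly balancing mortality losses.
Ricker and Ricker–Allee variants use the classic exponential maps,
decomposed into the same survivors + seeds form so that the
reproduce → disperse → recruit process order applies uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValueParseError


@dataclass
class LocalStep:
    """Survivors (integer) and pre-dispersal seeds (real) per cell."""

    survivors: np.ndarray
    seeds: np.ndarray


def effective_capacity(K, h):
    """Suitability-scaled carrying capacity K_h = K * h."""
    return np.asarray(K, dtype=float) * np.asarray(h, dtype=float)


def _as_arrays(N, *rest):
    arrs = [np.asarray(N, dtype=float)]
    arrs += [np.broadcast_to(np.asarray(x, dtype=float), arrs[0].shape) for x in rest]
    return arrs


def beverton_seeds(N, r, m, K_h):
    """Real-valued Beverton–Holt recruitment term.

    Zero wherever r <= m (no net reproductive surplus), K_h = 0 or m = 0
    (the calibrated denominator degenerates; the limit of the map is 0).
    """
    N, r, m, K_h = _as_arrays(N, r, m, K_h)
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        km = K_h * m
        # km > 0 also guards against subnormal underflow of the product,
        # whose limit (an infinitely strong density brake) is zero seeds
        valid = (r > m) & (km > 0)
        denom = np.where(valid, 1.0 + N * (r - m) / np.where(valid, km, 1.0), 1.0)
        seeds = np.where(valid & np.isfinite(denom), N * r / denom, 0.0)
    return seeds


def beverton_step(N, r, m, K_h) -> LocalStep:
    """One Beverton–Holt-with-mortality step (survivors floored)."""
    Na, ra, ma, Ka = _as_arrays(N, r, m, K_h)
    if np.any(Na < 0) or np.any(ma < 0) or np.any(ma > 1):
        raise ValueParseError("beverton_step: need N >= 0 and m in [0, 1]")
    survivors = np.floor(Na * (1.0 - ma))
    return LocalStep(survivors=survivors, seeds=beverton_seeds(Na, ra, ma, Ka))


def beverton_map(N, r, m, K_h):
    """Real-valued closed-cell composite N -> survivors + seeds.

    The analysis form of the update (no integerisation); iterating it
    from any N0 > 0 converges monotonically to K_h when r > m.
    """
    N, r, m, K_h = _as_arrays(N, r, m, K_h)
    return N * (1.0 - m) + beverton_seeds(N, r, m, K_h)


def ricker_step(N, r, m, K_h) -> LocalStep:
    """Classic Ricker map, decomposed into survivors + seeds.

    raw = N * exp(r * (1 - N/K_h)); seeds = max(0, raw - N*(1-m)), so
    the closed-cell composite equals the Ricker map whenever raw exceeds
    the survivor count.
    """
    Na, ra, ma, Ka = _as_arrays(N, r, m, K_h)
    if np.any(Na < 0) or np.any(ma < 0) or np.any(ma > 1):
        raise ValueParseError("ricker_step: need N >= 0 and m in [0, 1]")
    survivors = np.floor(Na * (1.0 - ma))
    ok = Ka > 0
    raw = np.where(ok, Na * np.exp(ra * (1.0 - Na / np.where(ok, Ka, 1.0))), 0.0)
    seeds = np.maximum(0.0, raw - Na * (1.0 - ma))
    seeds = np.where(ok, seeds, 0.0)
    return LocalStep(survivors=survivors, seeds=seeds)


def ricker_allee_step(N, r, m, K_h, A) -> LocalStep:
    """Ricker map with an Allee threshold A.

    raw = N * exp(r * (1 - N/K_h) * (N - A)/K_h): populations below A
    have negative exponent and decline deterministically.  A >= K is
    rejected at species validation, not here.
    """
    Na, ra, ma, Ka, Aa = _as_arrays(N, r, m, K_h, A)
    if np.any(Na < 0) or np.any(ma < 0) or np.any(ma > 1):
        raise ValueParseError("ricker_allee_step: need N >= 0 and m in [0, 1]")
    survivors = np.floor(Na * (1.0 - ma))
    ok = Ka > 0
    safe_K = np.where(ok, Ka, 1.0)
    raw = np.where(
        ok, Na * np.exp(ra * (1.0 - Na / safe_K) * ((Na - Aa) / safe_K)), 0.0
    )
    seeds = np.where(ok, np.maximum(0.0, raw - Na * (1.0 - ma)), 0.0)
    return LocalStep(survivors=survivors, seeds=seeds)


def local_step(model: str, N, fields, K_h) -> LocalStep:
    """Dispatch one local update by reproduction model name."""
    if model == "Beverton":
        return beverton_step(N, fields.growrate, fields.bevmort, K_h)
    if model == "Ricker":
        return ricker_step(N, fields.growrate, fields.bevmort, K_h)
    if model == "RickerAllee":
        if fields.allee is None:
            raise ValueParseError("RickerAllee model needs an allee threshold")
        return ricker_allee_step(
            N, fields.growrate, fields.bevmort, K_h, fields.allee
        )
    raise ValueParseError(f"unknown reproduction model {model!r}")
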