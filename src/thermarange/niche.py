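"""Habitat suitability from cardinal (min/opt/max) tolerance limits.

The response curve is the beta-type cardinal function used widely for
crop temperature responses: with tolerance window (v_min, v_opt, v_max),

    h(v) = ((v_max - v) / (v_max - v_opt))
           * ((v - v_min) / (v_opt - v_min)) ** ((v_opt - v_min) / (v_max - v_opt))

which equals 1 at v_opt, falls to 0 at both limits, and is set to exactly
0 outside [v_min, v_max].  Because the curve depends only on differences
of v, it is invariant to expressing temperature jointly in Celsius or
Kelvin.  Multiple niche variables combine by cell-wise product or
cell-wise minimum.
"""

from __future__ import annotations

import numpy as np

from .errors import EnvironmentShapeError, ValueParseError
from .io import CardinalLimits, EnvironmentSeries, SpeciesParams

#: Suitabilities below this are flushed to exactly zero so that
#: "suitable cell" predicates are stable against floating-point dust.
SUITABILITY_EPS = 1e-12


def tolerance_suitability(
    v_env: np.ndarray | float,
    v_min: float,
    v_opt: float,
    v_max: float,
) -> np.ndarray | float:
    """Cardinal tolerance suitability in [0, 1].

    Parameters
    ----------
    v_env
        Environmental value(s); NaN marks uninhabitable cells and maps to 0.
    v_min, v_opt, v_max
        Cardinal limits with ``v_min < v_opt < v_max`` (validated at
        species load time, not here).
    """
    v = np.asarray(v_env, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)

    inside = (v > v_min) & (v < v_max) & np.isfinite(v)
    h = np.zeros_like(v)
    if np.any(inside):
        vi = v[inside]
        exponent = (v_opt - v_min) / (v_max - v_opt)
        h[inside] = ((v_max - vi) / (v_max - v_opt)) * (
            (vi - v_min) / (v_opt - v_min)
        ) ** exponent
    np.clip(h, 0.0, 1.0, out=h)
    h[h < SUITABILITY_EPS] = 0.0
    return float(h[0]) if scalar else h


def species_suitability(limits: CardinalLimits, values) -> np.ndarray | float:
    """Suitability of ``values`` under a species' cardinal limits."""
    return tolerance_suitability(values, limits.lower, limits.optimum, limits.upper)


def combine_suitability(fields: list[np.ndarray], mode: str) -> np.ndarray:
    """Combine suitability layers cell-wise by product or minimum."""
    if not fields:
        raise ValueParseError("combine_suitability needs at least one field")
    shapes = {np.shape(f) for f in fields}
    if len(shapes) != 1:
        raise EnvironmentShapeError(f"suitability fields disagree in shape: {shapes}")
    if mode == "multiplication":
        combined = np.multiply.reduce(np.stack(fields), axis=0)
    elif mode == "minimum":
        combined = np.minimum.reduce(np.stack(fields), axis=0)
    else:
        raise ValueParseError(f"unknown combination mode {mode!r}")
    combined = np.clip(combined, 0.0, 1.0)
    combined[combined < SUITABILITY_EPS] = 0.0
    return combined


def apply_restriction(
    field: np.ndarray, restriction: np.ndarray | None, mode: str
) -> np.ndarray:
    """Fold a [0, 1] restriction layer into a suitability field.

    An absent restriction is a no-op.
    """
    if restriction is None:
        return field
    if np.nanmin(restriction) < 0 or np.nanmax(restriction) > 1:
        raise ValueParseError("restriction values must lie in [0, 1]")
    return combine_suitability([field, np.nan_to_num(restriction, nan=0.0)], mode)


def habitat_suitability(
    species: SpeciesParams,
    environment: EnvironmentSeries,
    t: int,
    attribute_mode: str = "minimum",
    restriction_mode: str = "minimum",
) -> np.ndarray:
    """Full per-cell habitat suitability at 1-based timestep ``t``.

    Tolerance curves are evaluated for every niche variable the species
    declares limits for; layers already expressed as suitability pass
    through unchanged; the restriction layer (if any) is applied last.
    NaN cells in any declared variable yield h = 0.
    """
    env = environment.slice(t)
    fields: list[np.ndarray] = []
    for name, limits in species.niche.items():
        if name not in env:
            continue  # species tolerates a variable the landscape lacks
        fields.append(np.asarray(species_suitability(limits, env[name])))
    for name in environment.suitability_names:
        fields.append(np.nan_to_num(env[name], nan=0.0))
    combined = combine_suitability(fields, attribute_mode)
    restriction = (
        environment.restriction[t - 1] if environment.restriction is not None else None
    )
    return apply_restriction(combined, restriction, restriction_mode)
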