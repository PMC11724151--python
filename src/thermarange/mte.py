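"""Metabolic scaling of demographic rates with body mass and temperature.

The metabolic theory of ecology expresses a biological rate Q as

    Q = b0 * m**a * exp(-E / (k * T))

with body mass ``m`` (g), allometric exponent ``a``, activation energy
``E`` (eV), Boltzmann constant ``k`` (eV/K) and absolute temperature
``T`` (K).  The normalisation constant ``b0`` is anchored to a known
reference value ``v`` of the rate at the species' optimum (reference)
temperature ``T_ref``:

    b0 = v / (m**a * exp(-E / (k * T_ref)))

so that Q(T_ref) = v exactly, and Q(T) = v * exp((E/k) * (1/T_ref - 1/T)).
Rates with E > 0 rise with temperature; carrying capacity conventionally
carries E < 0 and falls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValueParseError
from .io import SpeciesParams

#: Boltzmann constant in eV/K (CODATA), the MTE convention for E in eV.
BOLTZMANN_EV = 8.617333262e-5


@dataclass(frozen=True)
class MteSpec:
    """One metabolically scaled parameter: reference value + scaling law."""

    reference_value: float
    exponent: float
    activation_energy: float
    reference_temperature: float  # K

    def __post_init__(self) -> None:
        if self.reference_temperature <= 0:
            raise ValueParseError("reference temperature must be positive (K)")


def normalisation_constant(spec: MteSpec, mass: float) -> float:
    """Anchor b0 so the scaled rate reproduces the reference value at T_ref."""
    if mass <= 0:
        raise ValueParseError("mass must be > 0")
    return spec.reference_value / (
        mass**spec.exponent
        * np.exp(-spec.activation_energy / (BOLTZMANN_EV * spec.reference_temperature))
    )


def mte_rate(
    spec: MteSpec, b0: float, mass: float, temperature: np.ndarray | float
):
    """Evaluate Q = b0 * m^a * exp(-E/(kT)) at temperature(s) in Kelvin."""
    T = np.asarray(temperature, dtype=float)
    out = b0 * mass**spec.exponent * np.exp(
        -spec.activation_energy / (BOLTZMANN_EV * T)
    )
    return float(out) if np.ndim(temperature) == 0 else out


@dataclass
class DemographicFields:
    """Per-cell demographic parameters on the landscape grid."""

    growrate: np.ndarray
    bevmort: np.ndarray
    carry: np.ndarray
    allee: np.ndarray | None = None


def scale_demography(
    species: SpeciesParams,
    temperature: np.ndarray,
    use_metabolic_theory: bool = True,
) -> DemographicFields:
    """Demographic parameter grids for one temperature slice (Kelvin).

    With metabolic scaling on, each of growrate / bevmort / carry (and
    the Allee threshold, if the species has one) follows its own
    mass-and-temperature law anchored at the species' optimum
    temperature.  With it off, fields are constant at the reference
    values.  Mortality is clamped into [0, 1]; NaN (uninhabitable) cells
    get growrate 0, carry 0 and mortality 1.
    """
    T = np.asarray(temperature, dtype=float)
    habitable = np.isfinite(T)
    t_ref = species.niche["temperature"].optimum

    references = {
        "growrate": species.growrate,
        "bevmort": species.bevmort,
        "carry": species.carry,
    }
    if species.allee is not None:
        references["allee"] = species.allee

    fields: dict[str, np.ndarray] = {}
    for name, value in references.items():
        if use_metabolic_theory:
            coeff = species.mte[name]
            spec = MteSpec(value, coeff.exponent, coeff.activation_energy, t_ref)
            b0 = normalisation_constant(spec, species.mass)
            grid = np.where(habitable, mte_rate(spec, b0, species.mass, np.where(habitable, T, t_ref)), 0.0)
        else:
            grid = np.where(habitable, value, 0.0)
        fields[name] = grid

    growrate = fields["growrate"]
    carry = fields["carry"]
    bevmort = np.clip(fields["bevmort"], 0.0, 1.0)
    growrate[~habitable] = 0.0
    carry[~habitable] = 0.0
    bevmort = np.where(habitable, bevmort, 1.0)
    return DemographicFields(
        growrate=growrate,
        bevmort=bevmort,
        carry=carry,
        allee=fields.get("allee"),
    )
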