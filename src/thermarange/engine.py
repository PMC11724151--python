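"""Simulation engine: the per-timestep process chain and its bookkeeping.

Every timestep executes, in order:

1. habitat suitability from the current environment slice,
2. metabolic scaling of demographic rates from the current temperatures,
3. suitability-scaled carrying capacity K_h = K * h,
4. the local demographic step (survivors + pre-dispersal seeds),
5. kernel dispersal of seeds with absorbing edges,
6. recruitment (Poisson or deterministic floor),
7. next abundance = survivors + recruits.

Recorded outputs are the state *after* the step's update, together with
that step's habitat, K_h, growrate and bevmort fields.  Burn-in is not
engine logic: supply repeated environment slices before the onset of an
environmental trend.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .demography import effective_capacity, local_step
from .dispersal import DispersalKernel, build_kernel, disperse, recruit
from .errors import SpeciesParameterError, ValueParseError
from .io import (
    EnvironmentSeries,
    SimulationConfig,
    SimulationOutput,
    SpeciesParams,
)
from .mte import scale_demography
from .niche import habitat_suitability

logger = logging.getLogger("thermarange")

#: Occupancy probability of the ``random`` initialisation mode (an
#: arbitrary but fixed convention).
RANDOM_INIT_OCCUPANCY = 0.5


def initialise_abundance(
    species: SpeciesParams,
    suitability: np.ndarray,
    carry: np.ndarray,
    habitable: np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial abundance grid for one species.

    ``habitat``: N0 = round(K*h) wherever h > 0; ``all``: N0 = round(K)
    in every habitable cell regardless of suitability; ``random``: each
    suitable cell is independently occupied with probability 0.5 at
    N0 = round(K*h).
    """
    if mode == "habitat":
        n0 = np.where(suitability > 0, np.round(carry * suitability), 0.0)
    elif mode == "all":
        n0 = np.where(habitable, np.round(carry), 0.0)
    elif mode == "random":
        occupied = (suitability > 0) & (
            rng.random(suitability.shape) < RANDOM_INIT_OCCUPANCY
        )
        n0 = np.where(occupied, np.round(carry * suitability), 0.0)
    else:
        raise ValueParseError(f"unknown initialisation mode {mode!r}")
    return n0.astype(np.int64)


@dataclass
class SimulationState:
    """Mutable state of one single-species simulation."""

    config: SimulationConfig
    species: SpeciesParams
    environment: EnvironmentSeries
    rng: np.random.Generator
    kernel: DispersalKernel
    abundance: np.ndarray  # integer grid
    timestep: int = 0  # number of completed steps
    output: SimulationOutput | None = None
    _stacks: dict = field(default_factory=dict, repr=False)


def _habitable_mask(environment: EnvironmentSeries, t: int) -> np.ndarray:
    """Cells whose every environment layer is finite at timestep ``t``."""
    mask = np.ones(environment.shape, dtype=bool)
    for grid in environment.slice(t).values():
        mask &= np.isfinite(grid)
    return mask


def create_state(
    config: SimulationConfig,
    species: SpeciesParams,
    environment: EnvironmentSeries,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Validate inputs and build an initialised simulation state."""
    if config.reproduction_model == "Beverton" and not (
        species.growrate > species.bevmort
    ):
        raise SpeciesParameterError(
            f"{species.name}: Beverton dynamics need growrate > bevmort"
        )
    if config.reproduction_model == "RickerAllee" and species.allee is None:
        raise SpeciesParameterError(
            f"{species.name}: RickerAllee needs an 'allee' threshold"
        )
    if environment.timesteps < config.timesteps:
        raise ValueParseError(
            f"environment provides {environment.timesteps} slices for "
            f"{config.timesteps} timesteps"
        )
    if rng is None:
        rng = np.random.default_rng(config.randomseed)

    kernel = build_kernel(species.mean_dispersal_dist, species.max_dispersal_dist)
    h0 = habitat_suitability(
        species,
        environment,
        1,
        config.env_attribute_mode,
        config.env_restriction_mode,
    )
    fields0 = scale_demography(
        species,
        environment.slice(1)["temperature"],
        config.use_metabolic_theory,
    )
    habitable = _habitable_mask(environment, 1)
    abundance = initialise_abundance(
        species, h0, fields0.carry, habitable, config.initialise_cells, rng
    )

    T = config.timesteps
    rows, cols = environment.shape
    stacks = {
        "abundances": np.zeros((T, rows, cols), dtype=np.int64),
        "habitat": np.zeros((T, rows, cols)),
        "carry": np.zeros((T, rows, cols)),
        "growrate": np.zeros((T, rows, cols)),
        "bevmort": np.zeros((T, rows, cols)),
    }
    return SimulationState(
        config=config,
        species=species,
        environment=environment,
        rng=rng,
        kernel=kernel,
        abundance=abundance,
        _stacks=stacks,
    )


def simulate_timestep(state: SimulationState) -> SimulationState:
    """Advance the simulation by one timestep (in place)."""
    config = state.config
    t = state.timestep + 1
    if t > config.timesteps:
        raise ValueParseError("simulation already completed all timesteps")

    h = habitat_suitability(
        state.species,
        state.environment,
        t,
        config.env_attribute_mode,
        config.env_restriction_mode,
    )
    fields = scale_demography(
        state.species,
        state.environment.slice(t)["temperature"],
        config.use_metabolic_theory,
    )
    K_h = effective_capacity(fields.carry, h)

    step = local_step(config.reproduction_model, state.abundance, fields, K_h)
    arrivals = disperse(step.seeds, state.kernel)
    recruits = recruit(arrivals, config.use_stoch_num, state.rng)
    abundance = step.survivors.astype(np.int64) + recruits

    habitable = _habitable_mask(state.environment, t)
    abundance[~habitable] = 0

    state.abundance = abundance
    state._stacks["abundances"][t - 1] = abundance
    state._stacks["habitat"][t - 1] = h
    state._stacks["carry"][t - 1] = K_h
    state._stacks["growrate"][t - 1] = fields.growrate
    state._stacks["bevmort"][t - 1] = fields.bevmort
    state.timestep = t
    return state


def run_simulation(state: SimulationState) -> SimulationOutput:
    """Run all remaining timesteps, logging progress, and collect output."""
    start = time.perf_counter()
    while state.timestep < state.config.timesteps:
        simulate_timestep(state)
        logger.info(
            "%s: timestep %d/%d, total abundance %d",
            state.species.name,
            state.timestep,
            state.config.timesteps,
            int(state.abundance.sum()),
        )
    elapsed = time.perf_counter() - start
    logger.info(
        "%s: finished %d timesteps in %.2f s",
        state.species.name,
        state.config.timesteps,
        elapsed,
    )
    state.output = SimulationOutput(
        abundances=state._stacks["abundances"],
        habitat=state._stacks["habitat"],
        carry=state._stacks["carry"],
        growrate=state._stacks["growrate"],
        bevmort=state._stacks["bevmort"],
    )
    return state.output


def run_all(
    config: SimulationConfig,
    species: list[SpeciesParams],
    environment: EnvironmentSeries,
) -> dict[str, SimulationOutput]:
    """Run each species as an independent simulation on a shared landscape.

    The model simulates one species at a time; a single generator seeded
    from the configuration is consumed sequentially across species, so a
    whole multi-species batch is reproducible from one seed.
    """
    rng = np.random.default_rng(config.randomseed)
    outputs: dict[str, SimulationOutput] = {}
    for sp in species:
        state = create_state(config, sp, environment, rng=rng)
        outputs[sp.name] = run_simulation(state)
    return outputs


def abundance_change(
    output: SimulationOutput, t_from: int, t_to: int
) -> np.ndarray:
    """Signed per-cell abundance difference N(t_to) - N(t_from), 1-based."""
    if not (1 <= t_from < t_to <= output.timesteps):
        raise ValueParseError(
            f"need 1 <= t_from < t_to <= {output.timesteps}; "
            f"got ({t_from}, {t_to})"
        )
    return (
        output.abundances[t_to - 1].astype(np.int64)
        - output.abundances[t_from - 1].astype(np.int64)
    )


def suitability_change(
    output: SimulationOutput, t_from: int, t_to: int
) -> np.ndarray:
    """Companion per-cell habitat-suitability difference for change maps."""
    if not (1 <= t_from < t_to <= output.timesteps):
        raise ValueParseError(
            f"need 1 <= t_from < t_to <= {output.timesteps}; "
            f"got ({t_from}, {t_to})"
        )
    return output.habitat[t_to - 1] - output.habitat[t_from - 1]
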