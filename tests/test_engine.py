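"""Process-chain orchestration: ordering, initialisation, reproducibility."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from thermarange import (
    CardinalLimits,
    EnvironmentSeries,
    MteCoefficients,
    SimulationConfig,
    SpeciesParams,
    ValueParseError,
    abundance_change,
    build_kernel,
    create_state,
    disperse,
    effective_capacity,
    initialise_abundance,
    recruit,
    run_simulation,
    scale_demography,
    simulate_timestep,
    suitability_change,
)
from thermarange.demography import local_step
from thermarange.engine import SpeciesParameterError
from thermarange.niche import habitat_suitability
from thermarange.synth import climate_trend_series


def make_species(**overrides) -> SpeciesParams:
    params = dict(
        name="sp",
        carry=266667.0,
        growrate=1.15,
        bevmort=0.44,
        max_dispersal_dist=1,
        mean_dispersal_dist=0.0005,
        mass=10.0,
        niche={"temperature": CardinalLimits(280.0, 290.0, 300.0)},
    )
    params.update(overrides)
    return SpeciesParams(**params)


def make_config(**overrides) -> SimulationConfig:
    params = dict(
        config_dir=Path("."),
        temperature="temperature",
        timesteps=5,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def static_environment(grid: np.ndarray, timesteps: int) -> EnvironmentSeries:
    return EnvironmentSeries(
        variables={
            "temperature": np.broadcast_to(grid, (timesteps, *grid.shape)).copy()
        }
    )


class TestInitialise:
    def test_habitat_mode_rounds_capacity_times_suitability(self):
        h = np.array([[0.0, 0.5, 1.0]])
        carry = np.full((1, 3), 266667.0)
        rng = np.random.default_rng(0)
        n0 = initialise_abundance(
            make_species(), h, carry, np.ones_like(h, dtype=bool), "habitat", rng
        )
        assert n0[0, 0] == 0
        assert n0[0, 1] == round(266667.0 * 0.5)
        assert n0[0, 2] == 266667

    def test_all_and_habitat_coincide_on_fully_suitable_landscape(self):
        h = np.ones((3, 3))
        carry = np.full((3, 3), 1000.0)
        rng = np.random.default_rng(0)
        habitable = np.ones((3, 3), dtype=bool)
        a = initialise_abundance(make_species(), h, carry, habitable, "habitat", rng)
        b = initialise_abundance(make_species(), h, carry, habitable, "all", rng)
        np.testing.assert_array_equal(a, b)

    def test_random_mode_occupies_about_half_of_suitable_cells(self):
        h = np.ones((40, 40))
        carry = np.full((40, 40), 100.0)
        rng = np.random.default_rng(1)
        n0 = initialise_abundance(
            make_species(), h, carry, np.ones_like(h, dtype=bool), "random", rng
        )
        frac = (n0 > 0).mean()
        assert 0.4 < frac < 0.6

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueParseError):
            initialise_abundance(
                make_species(),
                np.ones((2, 2)),
                np.ones((2, 2)),
                np.ones((2, 2), dtype=bool),
                "everywhere",
                np.random.default_rng(0),
            )


class TestTimestep:
    def test_matches_scripted_composition_of_submodules(self):
        """One engine step equals the hand-scripted five-stage pipeline."""
        config = make_config(use_stoch_num=False)
        species = make_species(mean_dispersal_dist=1.0, max_dispersal_dist=2)
        grid = np.full((3, 3), 288.0)
        env = static_environment(grid, config.timesteps)
        state = create_state(config, species, env)
        n0 = state.abundance.copy()

        # oracle: explicit composition in the documented process order
        h = habitat_suitability(species, env, 1)
        fields = scale_demography(species, grid, True)
        K_h = effective_capacity(fields.carry, h)
        step = local_step("Beverton", n0, fields, K_h)
        arrivals = disperse(step.seeds, build_kernel(1.0, 2))
        recruits = recruit(arrivals, False)
        expected = step.survivors.astype(np.int64) + recruits

        simulate_timestep(state)
        np.testing.assert_array_equal(state.abundance, expected)
        np.testing.assert_array_equal(state._stacks["habitat"][0], h)
        np.testing.assert_array_equal(state._stacks["carry"][0], K_h)

    def test_negligible_dispersal_reduces_to_local_update(self):
        config = make_config()
        species = make_species()  # mean 0.0005, max 1: seeds stay home
        grid = np.full((4, 4), 287.0)
        env = static_environment(grid, config.timesteps)
        state = create_state(config, species, env)
        n0 = state.abundance.copy()

        h = habitat_suitability(species, env, 1)
        fields = scale_demography(species, grid, True)
        K_h = effective_capacity(fields.carry, h)
        step = local_step("Beverton", n0, fields, K_h)
        local_only = step.survivors.astype(np.int64) + np.floor(
            step.seeds
        ).astype(np.int64)

        simulate_timestep(state)
        assert np.abs(state.abundance - local_only).max() <= 1

    def test_equilibrium_cell_stays_near_capacity(self):
        config = make_config(timesteps=200)
        species = make_species()
        grid = np.full((1, 1), 290.0)  # optimum: h = 1, fields at reference
        env = static_environment(grid, 200)
        state = create_state(config, species, env)
        output = run_simulation(state)
        K = species.carry
        assert abs(output.abundances[-1, 0, 0] - K) / K < 0.005

    def test_extinction_is_absorbing(self):
        config = make_config(initialise_cells="habitat")
        species = make_species()
        grid = np.full((3, 3), 350.0)  # intolerably hot: h = 0 everywhere
        env = static_environment(grid, config.timesteps)
        state = create_state(config, species, env)
        assert state.abundance.sum() == 0
        output = run_simulation(state)
        assert output.abundances.sum() == 0


class TestRunSimulation:
    def test_output_has_configured_time_dimension(self):
        config = make_config(timesteps=7)
        env = static_environment(np.full((4, 5), 288.0), 7)
        output = run_simulation(create_state(config, make_species(), env))
        assert output.abundances.shape == (7, 4, 5)
        assert output.habitat.shape == (7, 4, 5)

    def test_single_timestep_runs(self):
        config = make_config(timesteps=1)
        env = static_environment(np.full((2, 2), 288.0), 1)
        output = run_simulation(create_state(config, make_species(), env))
        assert output.timesteps == 1

    def test_stochastic_runs_bit_identical_under_fixed_seed(self):
        def run_once():
            config = make_config(use_stoch_num=True, randomseed=77, timesteps=6)
            env = static_environment(np.full((5, 5), 288.0), 6)
            species = make_species(
                carry=500.0, mean_dispersal_dist=1.0, max_dispersal_dist=2
            )
            return run_simulation(create_state(config, species, env))

        a, b = run_once(), run_once()
        np.testing.assert_array_equal(a.abundances, b.abundances)
        np.testing.assert_array_equal(a.habitat, b.habitat)

    def test_beverton_requires_growth_exceeding_mortality(self):
        config = make_config()
        env = static_environment(np.full((2, 2), 288.0), 5)
        with pytest.raises(SpeciesParameterError):
            create_state(config, make_species(growrate=0.4), env)

    def test_uninhabitable_cells_stay_empty(self):
        config = make_config()
        grid = np.full((3, 3), 288.0)
        grid[1, 1] = np.nan
        env = static_environment(grid, config.timesteps)
        output = run_simulation(create_state(config, make_species(), env))
        assert np.all(output.abundances[:, 1, 1] == 0)
        assert np.all(output.habitat[:, 1, 1] == 0.0)


class TestAbundanceChange:
    def test_index_validation(self, small_output):
        with pytest.raises(ValueParseError):
            abundance_change(small_output, 1, 1)
        with pytest.raises(ValueParseError):
            abundance_change(small_output, 0, 3)
        with pytest.raises(ValueParseError):
            abundance_change(small_output, 2, 99)

    def test_static_equilibrium_change_is_tiny(self):
        config = make_config(timesteps=60)
        env = static_environment(np.full((2, 2), 290.0), 60)
        output = run_simulation(create_state(config, make_species(carry=1000.0), env))
        change = abundance_change(output, 40, 60)
        assert np.abs(change).max() <= 1

    def test_cooling_trend_with_positive_rate_energy_drives_decline(self):
        """Cooling pushes the metabolically scaled reproduction rate below
        mortality (E_r > 0, capacity and mortality held
        temperature-independent), so total abundance falls."""
        species = make_species(carry=2000.0)
        species.mte["bevmort"] = MteCoefficients(-0.25, 0.0)
        species.mte["carry"] = MteCoefficients(-0.75, 0.0)
        base = np.full((4, 4), 290.0)
        stack = climate_trend_series(base, 40, onset=11, delta_per_step=-0.3)
        env = EnvironmentSeries(variables={"temperature": stack})
        config = make_config(timesteps=40)
        output = run_simulation(create_state(config, species, env))
        change = abundance_change(output, 10, 40)
        assert change.sum() < 0
        assert suitability_change(output, 10, 40).sum() < 0
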