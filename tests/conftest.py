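"""Shared fixtures: tiny on-disk experiments built programmatically."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from thermarange import SimulationOutput, orchis_species_path
from thermarange.synth import write_grid_csv

ORCHIS_KEYS = {
    "carry": "266667",
    "growrate": "1.15",
    "bevmort": "0.44",
    "max_dispersal_dist": "1",
    "mean_dispersal_dist": "0.0005",
    "mass": "23.82",
    "lower_limit_temperature": "-3.36",
    "optimum_temperature": "10.2",
    "upper_limit_temperature": "15.28",
}


def write_keyvalue(path: Path, records: dict[str, str]) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{k},{v}\n" for k, v in records.items()))
    return path


@pytest.fixture
def orchis_file() -> Path:
    return orchis_species_path()


@pytest.fixture
def experiment(tmp_path):
    """Build a minimal runnable experiment folder; returns its config path.

    4x4 static landscape near the test species' optimum, one species,
    overridable config keys.
    """

    def _build(
        config_overrides: dict[str, str] | None = None,
        species_overrides: dict[str, str] | None = None,
        temperature_grid: np.ndarray | None = None,
    ) -> Path:
        root = tmp_path / "experiment"
        species = {
            "carry": "1000",
            "growrate": "1.15",
            "bevmort": "0.44",
            "max_dispersal_dist": "1",
            "mean_dispersal_dist": "0.5",
            "mass": "10",
            "lower_limit_temperature": "280",
            "optimum_temperature": "290",
            "upper_limit_temperature": "300",
        }
        species.update(species_overrides or {})
        write_keyvalue(root / "species" / "testsp.csv", species)

        if temperature_grid is None:
            temperature_grid = np.full((4, 4), 290.0)
        write_grid_csv(temperature_grid, root / "environment" / "temperature.csv")

        config = {"temperature": "temperature.csv", "timesteps": "5"}
        config.update(config_overrides or {})
        return write_keyvalue(root / "configuration.csv", config)

    return _build


@pytest.fixture
def small_output() -> SimulationOutput:
    """Deterministic synthetic output stack (5 timesteps, 2x3 grid)."""
    rng = np.random.default_rng(7)
    shape = (5, 2, 3)
    return SimulationOutput(
        abundances=rng.integers(0, 50, size=shape).astype(np.int64),
        habitat=rng.random(shape),
        carry=rng.random(shape) * 100,
        growrate=rng.random(shape) + 0.5,
        bevmort=rng.random(shape),
    )
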