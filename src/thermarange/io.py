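"""Input/output layer: configuration, species traits, environment grids, results.

All inputs are plain-text CSV.  Configuration and species files are
two-column, headerless ``key,value`` records; environment layers are
numeric matrices (one file per timestep, or a single file for a static
variable) where ``NA``/``NaN`` marks a permanently uninhabitable cell.
Results are written to a single long-format TSV with columns
``t, x, y, value, parameter`` (1-based coordinates, x = column, y = row).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EnvironmentShapeError,
    MissingInputError,
    MissingKeyError,
    SpeciesParameterError,
    UnknownKeyError,
    ValueParseError,
)

CELSIUS_OFFSET = 273.15
#: Temperatures whose mean exceeds this are assumed to be Kelvin already.
KELVIN_THRESHOLD = 150.0

REPRODUCTION_MODELS = ("Beverton", "Ricker", "RickerAllee")
COMBINE_MODES = ("multiplication", "minimum")
INITIALISE_MODES = ("habitat", "all", "random")

#: Output variables in the order they appear in the results file.  The
#: first column block is abundance, so the first data row of a run whose
#: first cell is empty reads ``1 1 1 0 abundance``.
OUTPUT_VARIABLES = ("abundance", "habitat", "carry", "growrate", "bevmort")


# ---------------------------------------------------------------------------
# key/value CSV primitives
# ---------------------------------------------------------------------------

def _read_keyvalue_csv(path: Path) -> dict[str, str]:
    """Read a two-column headerless ``key,value`` CSV into a dict."""
    if not path.is_file():
        raise MissingInputError(f"input file not found: {path}")
    records: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != 2:
                raise ValueParseError(
                    f"{path}:{lineno}: expected 'key,value', got {row!r}"
                )
            key = row[0].strip()
            if key in records:
                raise ValueParseError(f"{path}:{lineno}: duplicate key {key!r}")
            records[key] = row[1].strip()
    return records


def _parse_bool(raw: str, key: str) -> bool:
    low = raw.lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValueParseError(f"{key}: expected true/false, got {raw!r}")


def _parse_int(raw: str, key: str) -> int:
    try:
        return int(raw)
    except ValueError as exc:
        raise ValueParseError(f"{key}: expected integer, got {raw!r}") from exc


def _parse_float(raw: str, key: str) -> float:
    try:
        value = float(raw)
    except ValueError as exc:
        raise ValueParseError(f"{key}: expected number, got {raw!r}") from exc
    if not math.isfinite(value):
        raise ValueParseError(f"{key}: value must be finite, got {raw!r}")
    return value


def _parse_enum(raw: str, key: str, allowed: tuple[str, ...]) -> str:
    if raw not in allowed:
        raise ValueParseError(
            f"{key}: expected one of {', '.join(allowed)}; got {raw!r}"
        )
    return raw


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Resolved simulation configuration.

    Path-like fields (``output_dir``, ``species_dir``, ``environment_dir``)
    are kept relative in the file and resolved against the directory that
    contains the configuration file (``config_dir``).
    """

    config_dir: Path
    experiment_name: str = "default"
    output_dir: str = "./output/"
    species_dir: str = "./species/"
    environment_dir: str = "./environment/"
    input_backup: bool = False
    temperature: str | None = None
    precipitation: str | None = None
    restriction: str | None = None
    env_attribute_mode: str = "minimum"
    env_restriction_mode: str = "minimum"
    timesteps: int = 20
    randomseed: int = 42
    reproduction_model: str = "Beverton"
    use_metabolic_theory: bool = True
    use_stoch_num: bool = False
    initialise_cells: str = "habitat"
    #: Optional override of temperature unit detection: "C", "K" or None (auto).
    temperature_unit: str | None = None
    #: Optional grid-cell edge length, used only when reporting dispersal
    #: distances in kilometres.
    cell_size_km: float | None = None
    #: Extra pre-computed suitability layers, name -> path reference.
    suitability_layers: dict[str, str] = field(default_factory=dict)

    def resolved_species_dir(self) -> Path:
        return (self.config_dir / self.species_dir).resolve()

    def resolved_environment_dir(self) -> Path:
        return (self.config_dir / self.environment_dir).resolve()

    def resolved_output_dir(self) -> Path:
        return (self.config_dir / self.output_dir).resolve()


_CONFIG_PARSERS = {
    "experiment_name": lambda raw, key: raw,
    "config_dir": lambda raw, key: raw,  # accepted; actual path wins
    "output_dir": lambda raw, key: raw,
    "species_dir": lambda raw, key: raw,
    "environment_dir": lambda raw, key: raw,
    "input_backup": _parse_bool,
    "temperature": lambda raw, key: raw,
    "precipitation": lambda raw, key: raw,
    "restriction": lambda raw, key: raw,
    "env_attribute_mode": lambda raw, key: _parse_enum(raw, key, COMBINE_MODES),
    "env_restriction_mode": lambda raw, key: _parse_enum(raw, key, COMBINE_MODES),
    "timesteps": _parse_int,
    "randomseed": _parse_int,
    "reproduction_model": lambda raw, key: _parse_enum(raw, key, REPRODUCTION_MODELS),
    "use_metabolic_theory": _parse_bool,
    "use_stoch_num": _parse_bool,
    "initialise_cells": lambda raw, key: _parse_enum(raw, key, INITIALISE_MODES),
    "temperature_unit": lambda raw, key: _parse_enum(raw, key, ("C", "K")),
    "cell_size_km": _parse_float,
}


def read_config(path: str | Path) -> SimulationConfig:
    """Read and validate a configuration file.

    Unknown keys are rejected outright; keys of the form
    ``suitability_<name>`` declare extra pre-computed suitability layers.
    Missing keys fall back to the documented defaults.  The temperature
    layer reference is mandatory.
    """
    path = Path(path)
    records = _read_keyvalue_csv(path)
    config = SimulationConfig(config_dir=path.parent.resolve())

    for key, raw in records.items():
        if key.startswith("suitability_") and key != "suitability_":
            config.suitability_layers[key.removeprefix("suitability_")] = raw
            continue
        if key not in _CONFIG_PARSERS:
            raise UnknownKeyError(f"{path}: unknown configuration key {key!r}")
        if key == "config_dir":
            continue
        setattr(config, key, _CONFIG_PARSERS[key](raw, key))

    if config.temperature is None:
        raise MissingKeyError(f"{path}: required key 'temperature' is missing")
    if config.timesteps < 1:
        raise ValueParseError(
            f"timesteps: must be >= 1, got {config.timesteps}"
        )
    return config


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CardinalLimits:
    """Minimum / optimum / maximum tolerable value of one niche variable."""

    lower: float
    optimum: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.optimum < self.upper):
            raise SpeciesParameterError(
                "niche limits must satisfy lower < optimum < upper; got "
                f"({self.lower}, {self.optimum}, {self.upper})"
            )


@dataclass(frozen=True)
class MteCoefficients:
    """Allometric exponent ``a`` and activation energy ``E`` (eV) of one rate."""

    exponent: float
    activation_energy: float


#: Canonical metabolic-theory coefficients: biological *rates* scale with
#: mass^(-1/4) and rise with temperature (E = +0.65 eV); carrying capacity
#: scales with mass^(-3/4) and falls with temperature (E = -0.65 eV).
DEFAULT_MTE = {
    "growrate": MteCoefficients(-0.25, 0.65),
    "bevmort": MteCoefficients(-0.25, 0.65),
    "carry": MteCoefficients(-0.75, -0.65),
    "allee": MteCoefficients(-0.75, -0.65),
}


@dataclass
class SpeciesParams:
    """Species-specific traits driving demography, niche and dispersal.

    Temperature limits are stored in Kelvin; dispersal distances are in
    grid cells; ``carry`` is individuals per cell; ``growrate`` and
    ``bevmort`` are per-timestep reference rates at the species' optimum
    temperature; ``mass`` is in grams.
    """

    name: str
    carry: float
    growrate: float
    bevmort: float
    max_dispersal_dist: int
    mean_dispersal_dist: float
    mass: float
    niche: dict[str, CardinalLimits]
    mte: dict[str, MteCoefficients] = field(
        default_factory=lambda: dict(DEFAULT_MTE)
    )
    allee: float | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise SpeciesParameterError(f"{self.name}: mass must be > 0")
        if not 0.0 <= self.bevmort <= 1.0:
            raise SpeciesParameterError(
                f"{self.name}: bevmort must lie in [0, 1], got {self.bevmort}"
            )
        if self.carry < 0:
            raise SpeciesParameterError(f"{self.name}: carry must be >= 0")
        if self.max_dispersal_dist < 1:
            raise SpeciesParameterError(
                f"{self.name}: max_dispersal_dist must be at least 1"
            )
        if self.mean_dispersal_dist <= 0:
            raise SpeciesParameterError(
                f"{self.name}: mean_dispersal_dist must be > 0"
            )
        if "temperature" not in self.niche:
            raise SpeciesParameterError(
                f"{self.name}: temperature niche limits are required"
            )
        if self.allee is not None and self.allee >= self.carry:
            raise SpeciesParameterError(
                f"{self.name}: allee threshold must be below carry"
            )


def limits_to_kelvin(
    lower: float, optimum: float, upper: float, unit: str | None = None
) -> CardinalLimits:
    """Convert temperature limits to Kelvin.

    With ``unit=None`` the scale is auto-detected: limit means above
    ``KELVIN_THRESHOLD`` are taken as Kelvin already, which makes the
    conversion idempotent.
    """
    if unit is None:
        unit = "K" if (lower + optimum + upper) / 3.0 > KELVIN_THRESHOLD else "C"
    if unit == "C":
        return CardinalLimits(
            lower + CELSIUS_OFFSET, optimum + CELSIUS_OFFSET, upper + CELSIUS_OFFSET
        )
    return CardinalLimits(lower, optimum, upper)


_SPECIES_REQUIRED = (
    "carry",
    "growrate",
    "bevmort",
    "max_dispersal_dist",
    "mean_dispersal_dist",
    "mass",
    "lower_limit_temperature",
    "optimum_temperature",
    "upper_limit_temperature",
)
_SPECIES_OPTIONAL = (
    "lower_limit_precipitation",
    "optimum_precipitation",
    "upper_limit_precipitation",
    "allee",
    "exponent_growrate",
    "energy_growrate",
    "exponent_bevmort",
    "energy_bevmort",
    "exponent_carry",
    "energy_carry",
)
#: Accepted alias (a widespread misspelling in circulating trait files).
_SPECIES_ALIASES = {"mean_disperal_dist": "mean_dispersal_dist"}


def read_species_file(
    path: str | Path, temperature_unit: str | None = None
) -> SpeciesParams:
    """Parse one species trait file (one species per file)."""
    path = Path(path)
    records = _read_keyvalue_csv(path)
    records = {_SPECIES_ALIASES.get(k, k): v for k, v in records.items()}

    known = set(_SPECIES_REQUIRED) | set(_SPECIES_OPTIONAL)
    for key in records:
        if key not in known:
            raise UnknownKeyError(f"{path}: unknown species key {key!r}")
    for key in _SPECIES_REQUIRED:
        if key not in records:
            raise MissingKeyError(f"{path}: required species key {key!r} missing")

    get = lambda key: _parse_float(records[key], key)  # noqa: E731

    niche = {
        "temperature": limits_to_kelvin(
            get("lower_limit_temperature"),
            get("optimum_temperature"),
            get("upper_limit_temperature"),
            unit=temperature_unit,
        )
    }
    precip_keys = [k for k in records if k.endswith("_precipitation")]
    if precip_keys:
        if len(precip_keys) != 3:
            raise MissingKeyError(
                f"{path}: precipitation limits need all of lower/optimum/upper"
            )
        niche["precipitation"] = CardinalLimits(
            get("lower_limit_precipitation"),
            get("optimum_precipitation"),
            get("upper_limit_precipitation"),
        )

    mte = dict(DEFAULT_MTE)
    for rate in ("growrate", "bevmort", "carry"):
        exp_key, en_key = f"exponent_{rate}", f"energy_{rate}"
        if exp_key in records or en_key in records:
            mte[rate] = MteCoefficients(
                get(exp_key) if exp_key in records else DEFAULT_MTE[rate].exponent,
                get(en_key) if en_key in records else DEFAULT_MTE[rate].activation_energy,
            )
    mte["allee"] = mte["carry"]

    max_disp = _parse_int(records["max_dispersal_dist"], "max_dispersal_dist")
    return SpeciesParams(
        name=path.stem,
        carry=get("carry"),
        growrate=get("growrate"),
        bevmort=get("bevmort"),
        max_dispersal_dist=max_disp,
        mean_dispersal_dist=get("mean_dispersal_dist"),
        mass=get("mass"),
        niche=niche,
        mte=mte,
        allee=get("allee") if "allee" in records else None,
    )


def read_species(
    directory: str | Path, temperature_unit: str | None = None
) -> list[SpeciesParams]:
    """Read every species file in a directory (sorted by filename)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise MissingInputError(f"species directory not found: {directory}")
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".csv")
    if not files:
        raise MissingInputError(f"no species files in {directory}")
    return [read_species_file(p, temperature_unit) for p in files]


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentSeries:
    """Named stacks of environment grids, indexed ``[timestep, row, col]``.

    Temperature is stored in Kelvin.  NaN cells are permanently
    uninhabitable.  ``restriction`` (if present) and any layer listed in
    ``suitability_names`` are already suitabilities in [0, 1].
    """

    variables: dict[str, np.ndarray]
    restriction: np.ndarray | None = None
    suitability_names: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.variables.values()))
        return first.shape[1], first.shape[2]

    @property
    def timesteps(self) -> int:
        return next(iter(self.variables.values())).shape[0]

    def slice(self, t: int) -> dict[str, np.ndarray]:
        """Environment grids at 1-based timestep ``t``."""
        return {name: stack[t - 1] for name, stack in self.variables.items()}


def _natural_key(path: Path) -> tuple:
    """Sort key splitting filenames into text and integer runs (t2 < t10)."""
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts), path.name


def read_grid_csv(path: str | Path) -> np.ndarray:
    """Read one numeric CSV matrix; NA/NaN marks uninhabitable cells."""
    path = Path(path)
    if not path.is_file():
        raise MissingInputError(f"environment file not found: {path}")
    frame = pd.read_csv(
        path,
        header=None,
        na_values=["NA", "NaN", "nan", "na"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            raise ValueParseError(
                f"{path}: non-numeric cell value {bad.iloc[0]!r}"
            )
    return frame.to_numpy(dtype=float)


def _read_layer(ref: Path, timesteps: int) -> np.ndarray:
    """Assemble a [timesteps, rows, cols] stack from a file or folder."""
    if ref.is_dir():
        files = sorted(
            (p for p in ref.iterdir() if p.suffix.lower() == ".csv"),
            key=_natural_key,
        )
        if len(files) < timesteps:
            raise EnvironmentShapeError(
                f"{ref}: {len(files)} files but {timesteps} timesteps required"
            )
        grids = [read_grid_csv(p) for p in files[:timesteps]]
        shapes = {g.shape for g in grids}
        if len(shapes) != 1:
            raise EnvironmentShapeError(f"{ref}: mixed grid shapes {shapes}")
        return np.stack(grids)
    grid = read_grid_csv(ref)
    return np.broadcast_to(grid, (timesteps, *grid.shape)).copy()


def temperature_to_kelvin(stack: np.ndarray, unit: str | None = None) -> np.ndarray:
    """Convert a temperature stack to Kelvin (auto-detected by default)."""
    if unit is None:
        unit = "K" if np.nanmean(stack) > KELVIN_THRESHOLD else "C"
    return stack if unit == "K" else stack + CELSIUS_OFFSET


def read_environment(config: SimulationConfig) -> EnvironmentSeries:
    """Read all environment layers referenced by a configuration.

    Every layer must share one grid shape; folders must hold at least
    ``timesteps`` files (trailing extras are ignored); single files are
    replicated across time.
    """
    env_dir = config.resolved_environment_dir()
    refs: dict[str, str] = {"temperature": config.temperature}
    if config.precipitation:
        refs["precipitation"] = config.precipitation
    for name, ref in config.suitability_layers.items():
        refs[name] = ref

    variables: dict[str, np.ndarray] = {}
    for name, ref in refs.items():
        variables[name] = _read_layer(env_dir / ref, config.timesteps)

    shapes = {stack.shape for stack in variables.values()}
    if len(shapes) != 1:
        raise EnvironmentShapeError(
            f"environment layers disagree in shape: {shapes}"
        )

    variables["temperature"] = temperature_to_kelvin(
        variables["temperature"], config.temperature_unit
    )
    for name in config.suitability_layers:
        layer = variables[name]
        if np.nanmin(layer) < 0 or np.nanmax(layer) > 1:
            raise ValueParseError(
                f"suitability layer {name!r} has values outside [0, 1]"
            )

    restriction = None
    if config.restriction:
        restriction = _read_layer(env_dir / config.restriction, config.timesteps)
        if restriction.shape != next(iter(shapes)):
            raise EnvironmentShapeError("restriction layer shape mismatch")
        if np.nanmin(restriction) < 0 or np.nanmax(restriction) > 1:
            raise ValueParseError("restriction values must lie in [0, 1]")

    return EnvironmentSeries(
        variables=variables,
        restriction=restriction,
        suitability_names=tuple(config.suitability_layers),
    )


# ---------------------------------------------------------------------------
# simulation output
# ---------------------------------------------------------------------------

@dataclass
class SimulationOutput:
    """Per-timestep result stacks, each indexed ``[timestep, row, col]``."""

    abundances: np.ndarray  # integer
    habitat: np.ndarray
    carry: np.ndarray  # suitability-scaled carrying capacity K_h
    growrate: np.ndarray
    bevmort: np.ndarray

    @property
    def timesteps(self) -> int:
        return self.abundances.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.abundances.shape[1], self.abundances.shape[2]

    def field_by_name(self, name: str) -> np.ndarray:
        mapping = {
            "abundance": self.abundances,
            "abundances": self.abundances,
            "habitat": self.habitat,
            "carry": self.carry,
            "growrate": self.growrate,
            "bevmort": self.bevmort,
        }
        if name not in mapping:
            raise KeyError(f"unknown output variable {name!r}")
        return mapping[name]


def write_output_tsv(output: SimulationOutput, path: str | Path) -> Path:
    """Write results as one long-format TSV.

    One row per (parameter, timestep, cell); parameter-major, then t,
    then y (row), then x (column), all coordinates 1-based.
    """
    path = Path(path)
    frames = []
    for name in OUTPUT_VARIABLES:
        arr = output.field_by_name(name)
        T, R, C = arr.shape
        values = arr.reshape(-1)
        if name == "abundance":
            values = values.astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "t": np.repeat(np.arange(1, T + 1), R * C),
                    "x": np.tile(np.arange(1, C + 1), T * R),
                    "y": np.tile(np.repeat(np.arange(1, R + 1), C), T),
                    # object dtype keeps abundance integral in the file and
                    # floats at full (round-trippable) repr precision
                    "value": pd.Series(values, dtype=object),
                    "parameter": name,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_output_tsv(path: str | Path) -> SimulationOutput:
    """Inverse of :func:`write_output_tsv`."""
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    T = int(table["t"].max())
    R = int(table["y"].max())
    C = int(table["x"].max())
    stacks = {}
    for name in OUTPUT_VARIABLES:
        sub = table[table["parameter"] == name]
        arr = np.empty((T, R, C), dtype=float)
        arr[sub["t"] - 1, sub["y"] - 1, sub["x"] - 1] = sub["value"].to_numpy()
        stacks[name] = arr
    return SimulationOutput(
        abundances=stacks["abundance"].astype(np.int64),
        habitat=stacks["habitat"],
        carry=stacks["carry"],
        growrate=stacks["growrate"],
        bevmort=stacks["bevmort"],
    )
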