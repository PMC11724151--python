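"""Static visual and tabular exports of simulation results.

Every plotted number is also written as machine-readable CSV; images are
a convenience, the CSV grids and tables are the record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValueParseError
from .io import SimulationOutput

MAP_VARIABLES = ("abundances", "habitat", "carry", "growrate", "bevmort")


def totals_table(output: SimulationOutput) -> pd.DataFrame:
    """Per-timestep totals of abundance and carrying capacity K_h."""
    return pd.DataFrame(
        {
            "t": np.arange(1, output.timesteps + 1),
            "total_abundance": output.abundances.sum(axis=(1, 2)),
            "total_carry": output.carry.sum(axis=(1, 2)),
        }
    )


def plot_abundances(output: SimulationOutput, out_prefix: str | Path) -> tuple[Path, Path]:
    """Plot total abundance and total K_h over time; write PNG + CSV."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    table = totals_table(output)
    csv_path = out_prefix.with_suffix(".csv")
    table.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["t"], table["total_abundance"], label="total abundance")
    ax.plot(table["t"], table["total_carry"], "--", label="total carrying capacity")
    ax.set_xlabel("timestep")
    ax.set_ylabel("individuals")
    ax.legend()
    fig.tight_layout()
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path, csv_path


def export_map(
    output: SimulationOutput, variable: str, t: int, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Export one output variable at one timestep as image + CSV grid."""
    if variable not in MAP_VARIABLES:
        raise ValueParseError(
            f"unknown output variable {variable!r}; choose from {MAP_VARIABLES}"
        )
    if not 1 <= t <= output.timesteps:
        raise ValueParseError(
            f"timestep {t} out of range [1, {output.timesteps}]"
        )
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    grid = output.field_by_name(variable)[t - 1]
    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(grid).to_csv(csv_path, header=False, index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    image = ax.imshow(grid, origin="upper")
    ax.set_title(f"{variable}, t = {t}")
    fig.colorbar(image, ax=ax)
    fig.tight_layout()
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path, csv_path
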