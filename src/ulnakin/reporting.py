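"""Summary tables and parameter-versus-angle plots.

The summary table mirrors the clinical reporting layout: one block per
movement with rows for the extreme wrist positions and the per-wrist
motion range, columns for the five reported quantities, every cell a
``median (q1 to q3)`` string at one-decimal precision alongside its
machine-readable floats.

Writers are pure functions of their inputs: repeated runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .parameters import MovementLabel
from .pipeline import CohortSummary, _quartiles, motion_range

PARAMETER_LABELS = {
    "uv3d_mm": "3-D ulnar variance (mm)",
    "ucp_t_mm": "3-D ulnocarpal proximity triquetrum (mm)",
    "ucp_l_mm": "3-D ulnocarpal proximity lunate (mm)",
    "epi3d_pct": "3-D epicentre (%)",
    "mru3d_pct": "3-D modified radioulnar line (%)",
}

ANGLE_LABELS = {
    MovementLabel.FE: "sagittal CR angle (deg)",
    MovementLabel.RUD: "coronal CR angle (deg)",
    MovementLabel.PS: "UR angle (deg)",
}

# default extreme-position targets per movement (degrees)
DEFAULT_EXTREMES = {
    MovementLabel.RUD: {"25deg ulnar deviation": -25.0, "10deg radial deviation": 10.0},
    MovementLabel.FE: {"60deg extension": 60.0, "40deg flexion": -40.0},
    MovementLabel.PS: {"50deg supination": 50.0, "50deg pronation": -50.0},
}

_CELL_RE = re.compile(r"^(-?\d+\.\d) \((-?\d+\.\d) to (-?\d+\.\d)\)$")


def format_cell(median: float, q1: float, q3: float) -> str:
    return f"{median:.1f} ({q1:.1f} to {q3:.1f})"


def parse_cell(cell: str) -> tuple[float, float, float]:
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable summary cell {cell!r}")
    return tuple(float(g) for g in m.groups())


@dataclass
class Table1Layout:
    """Formatted summary table plus its machine-readable float values."""

    cells: pd.DataFrame    # strings, index = (movement, position), cols = params
    values: pd.DataFrame   # multi-col (param, stat in median/q1/q3)

    def to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, lineterminator="\n")

    def to_json(self, path: str | Path) -> None:
        doc = {}
        for (movement, position), row in self.values.iterrows():
            doc.setdefault(movement, {})[position] = {
                param: {
                    stat: (None if pd.isna(row[(param, stat)]) else float(row[(param, stat)]))
                    for stat in ("median", "q1", "q3")
                }
                for param in PARAMETER_LABELS
            }
        Path(path).write_text(json.dumps(doc, indent=1))


def summarize_ranges(series_list: list[pd.DataFrame]) -> dict[str, tuple[float, float, float]]:
    """Median (IQR) across wrists of each parameter's per-wrist range."""
    out = {}
    for param in PARAMETER_LABELS:
        ranges = []
        for s in series_list:
            v = s[param].dropna()
            if len(v):
                ranges.append(motion_range(v.values))
        if ranges:
            out[param] = _quartiles(np.asarray(ranges))
    return out


def write_summary_table(
    cohorts: dict[MovementLabel, dict[str, CohortSummary]],
    series_by_movement: dict[MovementLabel, list[pd.DataFrame]],
    extremes: dict[MovementLabel, dict[str, float]] | None = None,
) -> Table1Layout:
    """Assemble the movement × position summary table.

    At each extreme-angle target the nearest populated (unmasked) bin
    within one bin width supplies median/IQR; cells with no such bin are
    marked missing.  Range rows summarize per-wrist max-minus-min values.
    """
    extremes = extremes or DEFAULT_EXTREMES
    rows_cells = {}
    rows_vals = {}
    for movement, per_param in cohorts.items():
        movement = MovementLabel(movement)
        positions = dict(extremes.get(movement, {}))
        for pos_name, target in positions.items():
            cell_row, val_row = {}, {}
            for param, summary in per_param.items():
                ok = summary.table[~summary.table["masked"]]
                med = q1 = q3 = np.nan
                if not ok.empty:
                    k = (ok["bin_center"] - target).abs().idxmin()
                    if abs(ok.at[k, "bin_center"] - target) <= summary.bin_width:
                        med, q1, q3 = ok.at[k, "median"], ok.at[k, "q1"], ok.at[k, "q3"]
                cell_row[param] = "missing" if pd.isna(med) else format_cell(med, q1, q3)
                val_row[(param, "median")] = med
                val_row[(param, "q1")] = q1
                val_row[(param, "q3")] = q3
            rows_cells[(movement.value, pos_name)] = cell_row
            rows_vals[(movement.value, pos_name)] = val_row
        range_summary = summarize_ranges(series_by_movement.get(movement, []))
        cell_row, val_row = {}, {}
        for param in PARAMETER_LABELS:
            if param in range_summary:
                med, q1, q3 = range_summary[param]
                cell_row[param] = format_cell(med, q1, q3)
            else:
                med = q1 = q3 = np.nan
                cell_row[param] = "missing"
            val_row[(param, "median")] = med
            val_row[(param, "q1")] = q1
            val_row[(param, "q3")] = q3
        rows_cells[(movement.value, "Range")] = cell_row
        rows_vals[(movement.value, "Range")] = val_row

    cells = pd.DataFrame.from_dict(rows_cells, orient="index")
    cells.index.names = ["movement", "position"]
    values = pd.DataFrame.from_dict(rows_vals, orient="index")
    values.index.names = ["movement", "position"]
    values.columns = pd.MultiIndex.from_tuples(values.columns)
    return Table1Layout(cells[list(PARAMETER_LABELS)], values)


def plot_parameter_curves(
    cohort: CohortSummary,
    path: str | Path,
    dpi: int = 120,
) -> Path:
    """Median curve with IQR band versus wrist angle.

    Vertical dotted lines mark the angle interval covered by at least
    ``min_count`` wrists (bins outside it are masked and not drawn).
    """
    tab = cohort.table
    if tab.empty or tab["masked"].all() and tab["n_wrists"].sum() == 0:
        raise ValueError("empty cohort summary")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = tab[~tab["masked"]]
    if not ok.empty:
        ax.plot(ok["bin_center"], ok["median"], color="tab:blue", lw=1.5, label="median")
        ax.fill_between(ok["bin_center"], ok["q1"], ok["q3"], color="tab:blue", alpha=0.25,
                        label="IQR")
    edges = cohort.mask_edges()
    if edges is not None:
        for e in edges:
            ax.axvline(e, color="k", ls=":", lw=1)
    ax.set_xlabel(ANGLE_LABELS[cohort.movement])
    ax.set_ylabel(PARAMETER_LABELS.get(cohort.parameter, cohort.parameter))
    ax.set_title(f"{cohort.parameter} during {cohort.movement.value}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
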