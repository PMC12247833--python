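"""Per-cell, per-compartment intensity features and the cell table.

The cell table is a :class:`pandas.DataFrame` with one row per cell and
QuPath-compatible measurement column names (``"Nucleus: DAPI mean"``,
``"Cell: MARKER max"`` …) so that measurement tables exported from QuPath can
be used interchangeably. Statistics are computed on raw grey levels over the
exact pixel sets — no normalisation is applied. Downstream stages append
``class_*`` label columns, ``signed_distance_um`` and ``bin_index``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ChannelStack
from .segmentation import CellGeometry

__all__ = [
    "COMPARTMENTS",
    "STATISTICS",
    "measurement_column",
    "measure_cells",
    "clip_for_display",
    "read_cell_table",
    "write_cell_table",
]

COMPARTMENTS = ("Nucleus", "Cytoplasm", "Cell")
STATISTICS = ("mean", "median", "min", "max", "std")


def measurement_column(compartment: str, channel: str, statistic: str) -> str:
    """QuPath-style measurement column name, e.g. ``"Nucleus: DAPI max"``."""
    return f"{compartment}: {channel} {statistic}"


def _stats(values: np.ndarray) -> dict[str, float]:
    # Population std (divide by n); median of an even-sized set is the mean
    # of the two central order statistics (numpy's convention).
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "std": float(values.std(ddof=0)),
    }


def measure_cells(
    stack: ChannelStack, geometries: Sequence[CellGeometry]
) -> pd.DataFrame:
    """Compute {mean, median, min, max, std} per channel × compartment.

    Cytoplasm statistics are NaN (never silently zero) when a cell's
    cytoplasm pixel set is empty; an empty nucleus pixel set is an error.
    """
    h, w = stack.shape
    rows = []
    for geom in geometries:
        if len(geom.nucleus_pixels) == 0:
            raise ValueError(f"cell {geom.cell_id} has an empty nucleus pixel set")
        for pix in (geom.nucleus_pixels, geom.cell_pixels):
            if len(pix) and (
                pix[:, 0].min() < 0
                or pix[:, 1].min() < 0
                or pix[:, 0].max() >= h
                or pix[:, 1].max() >= w
            ):
                raise ValueError(f"cell {geom.cell_id} has pixels outside the image")
        row: dict[str, object] = {
            "cell_id": geom.cell_id,
            "image_id": stack.image_id,
            "centroid_x_um": geom.centroid_um[0],
            "centroid_y_um": geom.centroid_um[1],
            "nucleus_area_um2": geom.nucleus_area_um2,
        }
        cyto = geom.cytoplasm_pixels
        compartments = {
            "Nucleus": geom.nucleus_pixels,
            "Cytoplasm": cyto,
            "Cell": geom.cell_pixels,
        }
        for channel in stack.names:
            img = stack[channel]
            for comp, pix in compartments.items():
                if len(pix) == 0:
                    stats = {s: np.nan for s in STATISTICS}
                else:
                    stats = _stats(img[pix[:, 0], pix[:, 1]])
                for stat, value in stats.items():
                    row[measurement_column(comp, channel, stat)] = value
        rows.append(row)
    columns = [
        "cell_id",
        "image_id",
        "centroid_x_um",
        "centroid_y_um",
        "nucleus_area_um2",
    ] + [
        measurement_column(comp, ch, st)
        for ch in stack.names
        for comp in COMPARTMENTS
        for st in STATISTICS
    ]
    return pd.DataFrame(rows, columns=columns)


def clip_for_display(
    values: Iterable[float], low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Winsorize to the given percentiles, for histogram display only.

    Classification and distribution fitting always use the raw values.
    """
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if values.size == 0:
        raise ValueError("clip_for_display needs a non-empty input")
    lo, hi = np.percentile(values, [low_pct, high_pct])
    return np.clip(values, lo, hi)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table.to_csv(path, sep=sep, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table written by this package or exported from QuPath.

    Tolerates tab- or comma-separated files and maps the common QuPath
    identity columns (``Object ID``, ``Image``, ``Centroid X µm`` …) onto
    this package's names when present.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    qupath_aliases = {
        "Object ID": "cell_id",
        "Image": "image_id",
        "Centroid X µm": "centroid_x_um",
        "Centroid Y µm": "centroid_y_um",
        "Nucleus: Area µm^2": "nucleus_area_um2",
    }
    return table.rename(
        columns={k: v for k, v in qupath_aliases.items() if k in table.columns}
    )
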