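"""Regression design assembly: quadrat covariate means, climate averages,
neighborhood waiting times, and the analysis table.

The analysis table holds one row per included (established) quadrat with
the waiting-time response, the ten driver means, the two background
variables (year of first detection; mean waiting time over the surrounding
3x3 neighborhood, focal quadrat excluded) and the nested eco-region labels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gridding import GridSpec

__all__ = [
    "quadrat_covariate_means",
    "climate_20yr_average",
    "neighborhood_mean_waiting",
    "assemble_table",
    "DRIVER_COLUMNS",
    "BACKGROUND_COLUMNS",
]

logger = logging.getLogger(__name__)

DRIVER_COLUMNS = [
    "winter_temp",
    "spring_tmax",
    "summer_precip",
    "elevation",
    "host_basal_area",
    "pop_density",
    "wood_use",
    "highway_density",
    "anthro_frag",
    "natural_frag",
]
BACKGROUND_COLUMNS = ["detection_year", "neighbor_wait"]


def quadrat_covariate_means(
    layer: np.ndarray, layer_grid: GridSpec, quad_grid: GridSpec
) -> np.ndarray:
    """Mean layer value per quadrat.

    A layer cell contributes to the quadrat containing its center
    (half-open cells); NaN layer cells are excluded from the mean.  A
    quadrat overlapped by no cell centers comes out NaN and is logged.
    """
    if layer_grid.cell_size > quad_grid.cell_size:
        raise ValueError("layer resolution must be <= quadrat size")
    layer = np.asarray(layer, float)
    rows, cols = np.indices(layer.shape)
    cx = layer_grid.x0 + (cols + 0.5) * layer_grid.cell_size
    cy = layer_grid.y0 + (rows + 0.5) * layer_grid.cell_size
    qc = np.floor((cx - quad_grid.x0) / quad_grid.cell_size).astype(int)
    qr = np.floor((cy - quad_grid.y0) / quad_grid.cell_size).astype(int)
    ok = (
        (qc >= 0)
        & (qc < quad_grid.n_cols)
        & (qr >= 0)
        & (qr < quad_grid.n_rows)
        & ~np.isnan(layer)
    )
    sums = np.zeros((quad_grid.n_rows, quad_grid.n_cols))
    counts = np.zeros((quad_grid.n_rows, quad_grid.n_cols))
    np.add.at(sums, (qr[ok], qc[ok]), layer[ok])
    np.add.at(counts, (qr[ok], qc[ok]), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.warning("%d quadrats overlap no covariate cells", n_empty)
    return out


def climate_20yr_average(layers) -> np.ndarray:
    """Per-cell mean across a stack of annual layers on a common grid."""
    layers = [np.asarray(a, float) for a in layers]
    if len(layers) < 2:
        raise ValueError("need >= 2 annual layers")
    shape = layers[0].shape
    if any(a.shape != shape for a in layers[1:]):
        raise ValueError("annual layers are on mismatched grids")
    return np.mean(np.stack(layers), axis=0)


def neighborhood_mean_waiting(
    w: np.ndarray, include_focal: bool = False
) -> np.ndarray:
    """Mean waiting time over the 3x3 neighborhood of each quadrat.

    The focal quadrat is excluded by default ("surrounding" read as
    exclusive); missing neighbors (NaN) are ignored, and the result is NaN
    where no neighbor has a value.
    """
    w = np.asarray(w, float)
    padded = np.pad(w, 1, constant_values=np.nan)
    sums = np.zeros_like(w)
    counts = np.zeros_like(w)
    offsets = [
        (dr, dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if include_focal or (dr, dc) != (0, 0)
    ]
    for dr, dc in offsets:
        shifted = padded[1 + dr : 1 + dr + w.shape[0], 1 + dc : 1 + dc + w.shape[1]]
        valid = ~np.isnan(shifted)
        sums[valid] += shifted[valid]
        counts[valid] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def assemble_table(
    establishment: pd.DataFrame,
    covariates: dict[str, np.ndarray],
    labels: pd.DataFrame,
    include_focal_neighborhood: bool = False,
) -> pd.DataFrame:
    """Build the analysis table from the three keyed inputs.

    ``establishment`` is the per-quadrat table (row, col, detection_year,
    establishment_year, waiting_time, status); ``covariates`` maps driver
    name to a per-quadrat mean grid; ``labels`` holds (row, col, level2,
    level4).  Only INCLUDED quadrats are kept, the 3x3 neighborhood mean is
    computed from the full waiting-time grid, and rows with any missing
    field are dropped with a logged count.
    """
    if establishment.duplicated(["row", "col"]).any():
        raise ValueError("duplicate quadrat keys in establishment table")
    if labels.duplicated(["row", "col"]).any():
        raise ValueError("duplicate quadrat keys in label table")

    n_rows = int(labels["row"].max()) + 1
    n_cols = int(labels["col"].max()) + 1
    w_grid = np.full((n_rows, n_cols), np.nan)
    inc = establishment[establishment["status"] == "INCLUDED"]
    w_grid[inc["row"].to_numpy(int), inc["col"].to_numpy(int)] = inc[
        "waiting_time"
    ].to_numpy(float)
    neigh = neighborhood_mean_waiting(w_grid, include_focal_neighborhood)

    table = inc[["row", "col", "waiting_time", "detection_year"]].copy()
    table["neighbor_wait"] = neigh[
        table["row"].to_numpy(int), table["col"].to_numpy(int)
    ]
    for name, grid in covariates.items():
        grid = np.asarray(grid, float)
        table[name] = grid[table["row"].to_numpy(int), table["col"].to_numpy(int)]
    table = table.merge(labels, on=["row", "col"], how="left", validate="1:1")

    n_before = len(table)
    table = table.dropna().reset_index(drop=True)
    dropped = n_before - len(table)
    if dropped:
        logger.info("dropped %d rows with missing fields", dropped)
    return table
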