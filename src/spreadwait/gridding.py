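"""Trap-catch gridding: quadrat assignment, yearly medians, filters.

Converts raw trap-year records into per-quadrat yearly median-catch series,
after removing trap-years within 1.5 km of a same-year treatment, and
applies the inclusion filters that restrict the analysis to quadrats that
turned from uninvaded to established during the monitoring period.

Conventions (fixed and documented):

* grid cells are half-open ``[edge, edge + size)`` in both axes, so a point
  exactly on an edge belongs to the higher-index cell;
* the treatment buffer drops records *strictly* within ``radius`` of a
  footprint (a trap exactly 1500 m away is kept);
* the low-catch filter uses the total raw catch over all traps and years
  (not the sum of medians), checked before the pre-established filter;
* detection means a yearly median of at least one moth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "QuadratSeries",
    "Status",
    "InclusionStatus",
    "exclude_treated",
    "assign_quadrats",
    "median_series",
    "first_detection_year",
    "apply_inclusion_filters",
    "grid_traps",
    "write_series",
    "write_status",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Quadrat grid in planar meters; cells are half-open."""

    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 5000.0
    n_rows: int = 20
    n_cols: int = 20

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")


@dataclass
class QuadratSeries:
    """Per-quadrat yearly median catch with missing years as NaN."""

    row: int
    col: int
    years: np.ndarray  # full study span
    median: np.ndarray  # NaN where no traps reported
    n_traps: np.ndarray  # traps reporting per year
    total_catch: int  # raw sum of counts over all traps and years


class Status(str, Enum):
    INCLUDED = "INCLUDED"
    EXCLUDED_LOW_CATCH = "EXCLUDED_LOW_CATCH"
    EXCLUDED_PRE_ESTABLISHED = "EXCLUDED_PRE_ESTABLISHED"
    EXCLUDED_NEVER_ESTABLISHED = "EXCLUDED_NEVER_ESTABLISHED"


@dataclass
class InclusionStatus:
    row: int
    col: int
    status: Status
    detection_year: int | None


def exclude_treated(
    traps: pd.DataFrame, treatments, radius: float = 1500.0
) -> pd.DataFrame:
    """Drop trap-year records strictly within ``radius`` of a same-year
    treatment footprint.

    ``treatments`` is an iterable of objects with ``x``, ``y``,
    ``radius_m`` and ``year`` (disc footprints); the distance to the
    footprint is the distance to the center minus the disc radius.  Other
    years of the same trap are retained.
    """
    if radius < 0:
        raise ValueError("buffer radius must be >= 0")
    treatments = list(treatments)
    if not treatments or traps.empty:
        return traps.copy()
    drop = np.zeros(len(traps), dtype=bool)
    x = traps["x"].to_numpy(float)
    y = traps["y"].to_numpy(float)
    yr = traps["year"].to_numpy(int)
    for t in treatments:
        d = np.hypot(x - t.x, y - t.y) - t.radius_m
        drop |= (yr == t.year) & (d < radius)
    kept = traps.loc[~drop].reset_index(drop=True)
    if drop.any():
        logger.info("treatment buffer dropped %d trap-year records", drop.sum())
    return kept


def assign_quadrats(traps: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Annotate records with (row, col); out-of-extent records are dropped
    with a logged count."""
    col = np.floor((traps["x"].to_numpy(float) - grid.x0) / grid.cell_size)
    row = np.floor((traps["y"].to_numpy(float) - grid.y0) / grid.cell_size)
    inside = (
        (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    )
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("dropped %d trap records outside the grid extent", n_out)
    out = traps.loc[inside].copy()
    out["row"] = row[inside].astype(int)
    out["col"] = col[inside].astype(int)
    return out.reset_index(drop=True)


def median_series(
    traps: pd.DataFrame, grid: GridSpec, years: np.ndarray | None = None
) -> dict[tuple[int, int], QuadratSeries]:
    """Per quadrat-year median of counts over traps.

    Even trap counts use the mean of the two middle order statistics.
    Years with no reporting traps are missing (NaN).  The total raw catch
    is the straight sum of all counts in the quadrat over all years.
    """
    if "row" not in traps.columns:
        traps = assign_quadrats(traps, grid)
    if years is None:
        years = np.arange(traps["year"].min(), traps["year"].max() + 1)
    years = np.asarray(years)

    grouped = traps.groupby(["row", "col", "year"])["count"]
    med = grouped.median()
    n = grouped.size()
    totals = traps.groupby(["row", "col"])["count"].sum()

    out: dict[tuple[int, int], QuadratSeries] = {}
    for (r, c), total in totals.items():
        m = np.full(len(years), np.nan)
        nt = np.zeros(len(years), dtype=int)
        sub_m = med.loc[(r, c)]
        sub_n = n.loc[(r, c)]
        idx = np.searchsorted(years, sub_m.index.to_numpy())
        m[idx] = sub_m.to_numpy()
        nt[idx] = sub_n.to_numpy()
        out[(int(r), int(c))] = QuadratSeries(
            row=int(r),
            col=int(c),
            years=years,
            median=m,
            n_traps=nt,
            total_catch=int(total),
        )
    return out


def first_detection_year(series: QuadratSeries, threshold: float = 1.0) -> int | None:
    """Earliest year whose (non-missing) median is >= ``threshold``."""
    ok = ~np.isnan(series.median) & (series.median >= threshold)
    if not ok.any():
        return None
    return int(series.years[np.argmax(ok)])


def apply_inclusion_filters(
    series: QuadratSeries,
    low_catch_threshold: float = 10.0,
    detection_threshold: float = 1.0,
    low_catch_on_medians: bool = False,
) -> InclusionStatus:
    """Apply the two pre-establishment filters, in a fixed order.

    1. EXCLUDED_LOW_CATCH — total catch below ``low_catch_threshold``
       (raw trap totals by default; the sum of yearly medians when
       ``low_catch_on_medians``);
    2. EXCLUDED_PRE_ESTABLISHED — the first non-missing yearly median is
       already positive (likely established before monitoring began).

    Survivors are provisionally INCLUDED; the establishment stage demotes
    quadrats that never reach establishment to EXCLUDED_NEVER_ESTABLISHED.
    """
    total = (
        np.nansum(series.median)
        if low_catch_on_medians
        else series.total_catch
    )
    detection = first_detection_year(series, detection_threshold)
    if total < low_catch_threshold:
        return InclusionStatus(series.row, series.col, Status.EXCLUDED_LOW_CATCH, detection)
    observed = series.median[~np.isnan(series.median)]
    if observed.size and observed[0] > 0:
        return InclusionStatus(
            series.row, series.col, Status.EXCLUDED_PRE_ESTABLISHED, detection
        )
    return InclusionStatus(series.row, series.col, Status.INCLUDED, detection)


def grid_traps(
    traps: pd.DataFrame,
    grid: GridSpec,
    treatments=(),
    years: np.ndarray | None = None,
    buffer_m: float = 1500.0,
) -> tuple[dict[tuple[int, int], QuadratSeries], dict[tuple[int, int], InclusionStatus]]:
    """Full gridding stage: exclusion buffer -> quadrats -> medians -> filters."""
    kept = exclude_treated(traps, treatments, buffer_m)
    kept = assign_quadrats(kept, grid)
    series = median_series(kept, grid, years)
    status = {key: apply_inclusion_filters(s) for key, s in series.items()}
    return series, status


def write_series(
    series: dict[tuple[int, int], QuadratSeries], path: str | Path
) -> None:
    """Long-format table row,col,year,median,n_traps (missing years kept)."""
    frames = []
    for (r, c), s in sorted(series.items()):
        frames.append(
            pd.DataFrame(
                {
                    "row": r,
                    "col": c,
                    "year": s.years,
                    "median": s.median,
                    "n_traps": s.n_traps,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_status(
    status: dict[tuple[int, int], InclusionStatus], path: str | Path
) -> None:
    rows = [
        {
            "row": st.row,
            "col": st.col,
            "status": st.status.value,
            "detection_year": st.detection_year,
        }
        for _, st in sorted(status.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
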