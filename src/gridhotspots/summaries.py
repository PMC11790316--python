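"""Reporting surfaces: zonal area/population shares, exposure bins, exceedance, point overlay.

All operations are cell-aligned: they take the trend table (one category per
cell), the lattice, a population surface and the per-cell long-term exposure
mean, and aggregate by spatial unit and trend category.  Percentages are
relative to the unit's own totals, so each exhaustive category partition sums
to 100.  Exposure SD uses the divide-by-n convention throughout, matching the
S term of the Gi* statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gistar import AnnualFieldStack
from .lattice import GridLattice
from .trend import CATEGORIES

__all__ = [
    "long_term_average",
    "zonal_summary",
    "exposure_bins",
    "exceedance",
    "overlay_points",
]

# higher priority first, for radius > 0 point queries
_CATEGORY_PRIORITY = ("consistent", "emerging", "declining", "inconsistent")


def long_term_average(stack: AnnualFieldStack, cell_ids: np.ndarray) -> pd.DataFrame:
    """Per-cell mean and SD of exposure across the study years (SD: divide-by-n)."""
    if stack.n_years < 1:
        raise ValueError("empty stack")
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "mean": stack.values.mean(axis=0),
            "sd": stack.values.std(axis=0, ddof=0),
        }
    )


def _aligned(trend: pd.DataFrame, *frames: pd.DataFrame) -> pd.DataFrame:
    """Inner-join cell-aligned tables on cell_id, checking full coverage."""
    out = trend
    for f in frames:
        merged = out.merge(f, on="cell_id", how="inner", validate="one_to_one")
        if len(merged) != len(out):
            raise ValueError("inputs are not aligned on the same cells")
        out = merged
    return out


def zonal_summary(
    trend: pd.DataFrame,
    lattice: GridLattice,
    population: pd.DataFrame,
    long_term: pd.DataFrame,
    units: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-unit, per-category cell counts, area/population shares and exposure.

    ``units`` maps cell_id → unit label; when omitted the whole lattice is one
    unit ("all").  Every (unit, category) pair is emitted, with zeros for
    empty categories, so shares always partition 100% of each unit.
    """
    df = trend[["cell_id", "category"]].merge(
        population[["cell_id", "population"]], on="cell_id", validate="one_to_one"
    )
    df = df.merge(long_term[["cell_id", "mean"]], on="cell_id", validate="one_to_one")
    if len(df) != len(trend):
        raise ValueError("population/exposure tables do not cover the trend cells")
    if units is None:
        df["unit"] = "all"
    else:
        df = df.merge(units[["cell_id", "unit"]], on="cell_id", validate="one_to_one", how="left")
        if df["unit"].isna().any():
            raise ValueError("cells missing a unit assignment")

    area = lattice.area_per_cell
    rows = []
    for unit, sub in df.groupby("unit", sort=True):
        n_unit = len(sub)
        pop_unit = float(sub["population"].sum())
        for cat in CATEGORIES:
            cells = sub[sub["category"] == cat]
            n = len(cells)
            pop = float(cells["population"].sum())
            mean_exp = float(cells["mean"].mean()) if n else 0.0
            sd_exp = float(cells["mean"].std(ddof=0)) if n else 0.0
            rows.append(
                {
                    "unit": unit,
                    "category": cat,
                    "n_cells": n,
                    "area": n * area,
                    "area_pct": 100.0 * n / n_unit,
                    "population": pop,
                    "population_pct": 100.0 * pop / pop_unit if pop_unit > 0 else 0.0,
                    "mean_exposure": mean_exp,
                    "sd_exposure": sd_exp,
                }
            )
    return pd.DataFrame(rows)


def _bin_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.floor(values.max() / bin_width) * bin_width + bin_width
    return np.arange(lo, hi + 0.5 * bin_width, bin_width)


def exposure_bins(
    trend: pd.DataFrame,
    long_term: pd.DataFrame,
    population: pd.DataFrame,
    lattice: GridLattice,
    *,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Per-category histogram of long-term means, as area % and population mass.

    Bins are half-open ``[lo, hi)`` with edges at multiples of ``bin_width``
    (default 10 exposure units) covering the observed range of each category.
    ``area_pct`` is relative to the category's own area.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    df = _aligned(trend[["cell_id", "category"]], long_term[["cell_id", "mean"]], population[["cell_id", "population"]])
    rows = []
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        if sub.empty:
            continue
        means = sub["mean"].to_numpy()
        pops = sub["population"].to_numpy()
        edges = _bin_edges(means, bin_width)
        which = np.digitize(means, edges) - 1  # [lo, hi) per np.digitize(right=False)
        for b in range(len(edges) - 1):
            in_bin = which == b
            rows.append(
                {
                    "category": cat,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n_cells": int(in_bin.sum()),
                    "area_pct": 100.0 * in_bin.sum() / len(sub),
                    "population": float(pops[in_bin].sum()),
                }
            )
    return pd.DataFrame(rows, columns=["category", "bin_lo", "bin_hi", "n_cells", "area_pct", "population"])


def exceedance(
    long_term: pd.DataFrame,
    trend: pd.DataFrame,
    population: pd.DataFrame,
    *,
    threshold: float = 40.0,
) -> pd.DataFrame:
    """Per-category share of cells and population with long-term mean strictly above ``threshold``.

    The default threshold of 40 exposure units corresponds to the Indian
    annual NAAQS for PM2.5.
    """
    df = _aligned(trend[["cell_id", "category"]], long_term[["cell_id", "mean"]], population[["cell_id", "population"]])
    rows = []
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        above = sub[sub["mean"] > threshold]
        rows.append(
            {
                "category": cat,
                "threshold": threshold,
                "n_cells": len(sub),
                "pct_cells_above": 100.0 * len(above) / len(sub) if len(sub) else 0.0,
                "population_above": float(above["population"].sum()),
            }
        )
    return pd.DataFrame(rows)


def overlay_points(
    points: pd.DataFrame,
    trend: pd.DataFrame,
    lattice: GridLattice,
    *,
    radius: int = 0,
) -> pd.DataFrame:
    """Tag each point with the trend category of its containing cell.

    Points carry ground coordinates ``x`` (eastward) and ``y`` (southward
    from the top edge, matching raster row order); the containing cell is
    ``(row, col) = (floor(y / cell_size), floor(x / cell_size))``.  With
    ``radius > 0`` the tag is the highest-priority category (consistent >
    emerging > declining > inconsistent) within the Chebyshev radius.
    Points outside the lattice, or on no valid cell, are tagged "outside".
    """
    for col in ("x", "y"):
        if col not in points.columns:
            raise ValueError(f"points table lacks column {col!r}")
        if not np.isfinite(points[col].to_numpy(float)).all():
            raise ValueError("malformed point coordinates")
    cat_by_cell = trend.set_index("cell_id")["category"]
    size = lattice.cell_size
    rank = {c: i for i, c in enumerate(_CATEGORY_PRIORITY)}

    out = points.copy()
    rows = np.floor(points["y"].to_numpy(float) / size).astype(int)
    cols = np.floor(points["x"].to_numpy(float) / size).astype(int)
    tags = []
    for r, c in zip(rows, cols):
        if not (0 <= r < lattice.n_rows and 0 <= c < lattice.n_cols):
            tags.append("outside")
            continue
        best = None
        for rr in range(max(0, r - radius), min(lattice.n_rows, r + radius + 1)):
            for cc in range(max(0, c - radius), min(lattice.n_cols, c + radius + 1)):
                if not lattice.valid[rr, cc]:
                    continue
                cat = cat_by_cell.get(rr * lattice.n_cols + cc)
                if cat is None:
                    continue
                if best is None or rank[cat] < rank[best]:
                    best = cat
        tags.append(best if best is not None else "outside")
    out["row"], out["col"], out["category"] = rows, cols, tags
    return out
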