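"""Regular-grid analysis lattice and queen-contiguity spatial weights.

The analysis unit is a rectangular raster of square cells, some of which may
be invalid (no-data: water bodies, missing predictors, masked cells).  Valid
cells are identified by a stable integer ``cell_id = row * n_cols + col`` and
ordered row-major.  Contiguity is *queen*: two valid cells are neighbors when
they share an edge or a corner (up to 8 neighbors).  Weights are binary; the
focal cell itself may carry weight 1 as well (``include_self``), which is the
defining feature of the Gi-star variant of the Getis-Ord statistic.

Cells whose neighbor set is empty after masking are pruned, iterating to a
fixed point because a removal can orphan a previously connected cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["GridLattice", "NeighborWeights", "build_lattice", "queen_neighbors", "prune_empty"]

# (drow, dcol) offsets of the 8 queen-contiguous cells
_QUEEN_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class GridLattice:
    """A rectangular lattice of square cells with a validity mask.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape. Row 0 is the north/top row of the raster.
    valid
        Boolean array of shape ``(n_rows, n_cols)``; True marks analysed cells.
    cell_size
        Side length of a cell in ground units (default 1.0, i.e. unit cells).
    """

    n_rows: int
    n_cols: int
    valid: np.ndarray = field(repr=False)
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        valid = np.asarray(self.valid, dtype=bool)
        if valid.shape != (self.n_rows, self.n_cols):
            raise ValueError("valid mask shape does not match lattice dimensions")
        if not valid.any():
            raise ValueError("lattice has no valid cells")
        object.__setattr__(self, "valid", valid)

    # -- identity -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        """Number of valid cells."""
        return int(self.valid.sum())

    @property
    def cell_ids(self) -> np.ndarray:
        """Row-major ids (``row * n_cols + col``) of valid cells, ascending."""
        return np.flatnonzero(self.valid.ravel())

    @property
    def area_per_cell(self) -> float:
        return float(self.cell_size) ** 2

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) index arrays aligned with :attr:`cell_ids`."""
        ids = self.cell_ids
        return ids // self.n_cols, ids % self.n_cols

    def positions_of(self, cell_ids: np.ndarray) -> np.ndarray:
        """Map cell ids to positions in the valid-cell ordering."""
        pos = np.searchsorted(self.cell_ids, cell_ids)
        ok = (pos < self.n_cells) & (self.cell_ids[np.minimum(pos, self.n_cells - 1)] == cell_ids)
        if not np.all(ok):
            raise KeyError("cell id not in lattice")
        return pos

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_array(cls, values: np.ndarray, *, nodata: float | None = None, cell_size: float = 1.0) -> "GridLattice":
        """Build from a 2-D value array; NaN (and optionally ``nodata``) marks invalid cells."""
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D array")
        valid = ~np.isnan(arr)
        if nodata is not None:
            valid &= arr != nodata
        return cls(arr.shape[0], arr.shape[1], valid, cell_size)

    @classmethod
    def from_cell_table(cls, table: pd.DataFrame, *, n_rows: int | None = None, n_cols: int | None = None, cell_size: float = 1.0) -> "GridLattice":
        """Build from a cell table with columns ``row``, ``col`` and optional ``valid``."""
        if table.empty:
            raise ValueError("empty cell table")
        rows = table["row"].to_numpy(int)
        cols = table["col"].to_numpy(int)
        if rows.min() < 0 or cols.min() < 0:
            raise ValueError("negative row/col index")
        nr = n_rows if n_rows is not None else int(rows.max()) + 1
        nc = n_cols if n_cols is not None else int(cols.max()) + 1
        valid = np.zeros((nr, nc), dtype=bool)
        flag = table["valid"].to_numpy(bool) if "valid" in table.columns else np.ones(len(table), bool)
        valid[rows[flag], cols[flag]] = True
        return cls(nr, nc, valid, cell_size)

    def subset(self, keep_positions: np.ndarray) -> "GridLattice":
        """New lattice keeping only the given positions of the valid ordering."""
        valid = np.zeros_like(self.valid)
        valid.ravel()[self.cell_ids[keep_positions]] = True
        return GridLattice(self.n_rows, self.n_cols, valid, self.cell_size)


@dataclass(frozen=True)
class NeighborWeights:
    """Binary queen-contiguity weights stored as a sparse adjacency graph.

    ``graph`` holds the non-self adjacencies (symmetric, 0/1, CSR) over the
    valid-cell positions of ``lattice``; ``include_self`` adds an implicit
    weight of 1 on the focal cell, as the Gi-star statistic requires.
    """

    graph: sp.csr_matrix = field(repr=False)
    include_self: bool = True

    @property
    def n_cells(self) -> int:
        return self.graph.shape[0]

    @property
    def n_effective(self) -> int:
        return self.n_cells

    @property
    def counts(self) -> np.ndarray:
        """Non-self neighbor count per cell."""
        return np.diff(self.graph.indptr)

    def neighbors(self, position: int) -> np.ndarray:
        """Positions of the non-self neighbors of one cell."""
        g = self.graph
        return g.indices[g.indptr[position]:g.indptr[position + 1]]

    def weights_matrix(self) -> sp.csr_matrix:
        """Full weight matrix, with the self-weight on the diagonal if enabled."""
        if self.include_self:
            return (self.graph + sp.identity(self.n_cells, dtype=self.graph.dtype, format="csr")).tocsr()
        return self.graph

    def row_sums(self) -> np.ndarray:
        """Sum of weights per cell (``Σ_j w_ij``); binary weights, so also ``Σ_j w_ij²``."""
        return self.counts + (1 if self.include_self else 0)

    def check_symmetry(self) -> bool:
        return (self.graph != self.graph.T).nnz == 0


def build_lattice(source, *, nodata: float | None = None, cell_size: float = 1.0) -> GridLattice:
    """Build a :class:`GridLattice` from a 2-D array or a cell table.

    Arrays use NaN (and optionally a ``nodata`` sentinel) for invalid cells;
    DataFrames need ``row``/``col`` columns and an optional ``valid`` flag.
    """
    if isinstance(source, pd.DataFrame):
        return GridLattice.from_cell_table(source, cell_size=cell_size)
    return GridLattice.from_array(np.asarray(source), nodata=nodata, cell_size=cell_size)


def queen_neighbors(lattice: GridLattice, *, include_self: bool = True) -> NeighborWeights:
    """Queen-contiguity binary weights over the valid cells of ``lattice``.

    Each cell is linked to the up-to-8 valid cells sharing an edge or corner
    with it.  The adjacency is built by shifting the validity mask along the
    eight offsets, so memory stays linear in the number of adjacencies.
    """
    valid = lattice.valid
    n_rows, n_cols = lattice.n_rows, lattice.n_cols
    pos = np.full(valid.shape, -1, dtype=np.int64)
    pos[valid] = np.arange(lattice.n_cells)

    src, dst = [], []
    for dr, dc in _QUEEN_OFFSETS:
        r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
        c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
        here = valid[r0:r1, c0:c1]
        there = valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        both = here & there
        src.append(pos[r0:r1, c0:c1][both])
        dst.append(pos[r0 + dr:r1 + dr, c0 + dc:c1 + dc][both])
    i = np.concatenate(src) if src else np.empty(0, np.int64)
    j = np.concatenate(dst) if dst else np.empty(0, np.int64)
    n = lattice.n_cells
    graph = sp.csr_matrix((np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n))
    return NeighborWeights(graph=graph, include_self=include_self)


def prune_empty(weights: NeighborWeights, lattice: GridLattice) -> tuple[NeighborWeights, GridLattice]:
    """Remove cells with no non-self neighbors, iterating to a fixed point.

    A removed cell can orphan a neighbor that had only that one contact, so
    pruning repeats until no empty neighbor set remains.  Raises if every
    cell would be removed.
    """
    graph = weights.graph
    keep_global = np.arange(weights.n_cells)
    while True:
        counts = np.diff(graph.indptr)
        keep = counts > 0
        if keep.all():
            break
        if not keep.any():
            raise ValueError("degenerate lattice: pruning removed all cells")
        graph = graph[keep][:, keep].tocsr()
        keep_global = keep_global[keep]
    if len(keep_global) == weights.n_cells:
        return weights, lattice
    return (
        NeighborWeights(graph=graph, include_self=weights.include_self),
        lattice.subset(keep_global),
    )
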