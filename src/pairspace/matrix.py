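"""Contact-matrix view of the interaction space.

A :class:`ContactMatrix` represents interactions as a grid whose rows and
columns are genomic regions (indices into a shared region set) and whose
cells hold interaction values.  Cells may be *empty*, which is distinct
from holding numeric zero.  Two backends are supported:

- ``dense``: a full value grid plus a boolean filled-mask;
- ``sparse``: a ``scipy.sparse`` matrix storing only non-empty cells, with
  "empty" represented by structural absence.  Because a stored zero would
  be indistinguishable from an empty cell on conversion back, stored zeros
  are rejected in the sparse backend; this keeps the two backends
  logically equivalent.

:func:`inflate` builds a matrix from an interaction table by *exact
coordinate identity* between anchors and the requested row/column regions
(not by overlap — binning is the caller's job), so that
:func:`deflate` is its lossless inverse on the non-empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .interactions import InteractionTable, canonical_sort, make_interactions
from .regions import GenomicRegion, RegionSet, ValidationError, build_region_set

__all__ = ["ContactMatrix", "inflate", "deflate", "transpose_cm"]

BACKENDS = ("dense", "sparse")


@dataclass(frozen=True, eq=False)
class ContactMatrix:
    """Row/column anchor indices into a region set plus a value grid.

    ``values`` is an r x c float array and ``filled`` the same-shape boolean
    mask of non-empty cells (dense backend), or a ``scipy.sparse`` matrix
    whose stored entries are exactly the non-empty cells (sparse backend).
    """

    region_set: RegionSet
    row_indices: np.ndarray
    col_indices: np.ndarray
    values: np.ndarray | sp.spmatrix
    filled: np.ndarray | None = None
    backend: str = "dense"

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValidationError(f"backend must be one of {BACKENDS}, got {self.backend!r}")
        rows = np.asarray(self.row_indices, dtype=np.int64)
        cols = np.asarray(self.col_indices, dtype=np.int64)
        n = len(self.region_set)
        for name, arr in (("row_indices", rows), ("col_indices", cols)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValidationError(f"{name} out of range for region set of size {n}")
        shape = (len(rows), len(cols))
        if self.backend == "dense":
            vals = np.asarray(self.values, dtype=float)
            filled = (
                np.ones(shape, dtype=bool)
                if self.filled is None
                else np.asarray(self.filled, dtype=bool)
            )
            if vals.shape != shape or filled.shape != shape:
                raise ValidationError(
                    f"grid shape {vals.shape} / mask shape {filled.shape} do not match "
                    f"index lengths {shape}"
                )
            object.__setattr__(self, "values", vals)
            object.__setattr__(self, "filled", filled)
        else:
            vals = sp.csr_matrix(self.values, dtype=float)
            if vals.shape != shape:
                raise ValidationError(
                    f"sparse grid shape {vals.shape} does not match index lengths {shape}"
                )
            if vals.nnz and np.any(vals.data == 0):
                raise ValidationError(
                    "sparse backend cannot store explicit zeros (indistinguishable from empty)"
                )
            object.__setattr__(self, "values", vals)
            object.__setattr__(self, "filled", None)
        object.__setattr__(self, "row_indices", rows)
        object.__setattr__(self, "col_indices", cols)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_indices), len(self.col_indices))

    def row_regions(self) -> list[GenomicRegion]:
        return [self.region_set[i] for i in self.row_indices]

    def col_regions(self) -> list[GenomicRegion]:
        return [self.region_set[i] for i in self.col_indices]

    def filled_mask(self) -> np.ndarray:
        """Dense boolean mask of non-empty cells, whatever the backend."""
        if self.backend == "dense":
            return self.filled.copy()
        mask = np.zeros(self.shape, dtype=bool)
        coo = self.values.tocoo()
        mask[coo.row, coo.col] = True
        return mask

    def dense_values(self) -> np.ndarray:
        """Dense value grid with NaN in empty cells."""
        out = np.full(self.shape, np.nan)
        if self.backend == "dense":
            out[self.filled] = self.values[self.filled]
        else:
            coo = self.values.tocoo()
            out[coo.row, coo.col] = coo.data
        return out


def inflate(
    table: InteractionTable,
    row_regions: Sequence[GenomicRegion],
    col_regions: Sequence[GenomicRegion],
    values: Sequence[float],
    combine: str = "error",
    backend: str = "dense",
) -> ContactMatrix:
    """Project interaction values onto a row-region x column-region grid.

    Cell (i, j) receives the value of any interaction whose anchor
    coordinates equal ``row_regions[i]`` and ``col_regions[j]`` exactly, in
    either anchor order; a single interaction therefore fills both (i, j)
    and (j, i) when both orderings exist in the grid.  Cells no interaction
    maps to stay empty.  When several *distinct* interactions map to one
    cell, ``combine`` resolves them: ``"error"`` (default) raises,
    ``"sum"`` adds, ``"first"`` keeps the first in table order.
    """
    if combine not in ("error", "sum", "first"):
        raise ValueError(f"combine must be 'error', 'sum' or 'first', got {combine!r}")
    values = np.asarray(values, dtype=float)
    if values.shape != (len(table),):
        raise ValidationError(
            f"values has shape {values.shape}; expected ({len(table)},)"
        )
    row_regions = list(row_regions)
    col_regions = list(col_regions)
    rset, index_map = build_region_set(
        row_regions + col_regions, chrom_order=table.region_set.chrom_order
    )
    rows = np.asarray(index_map[: len(row_regions)], dtype=np.int64)
    cols = np.asarray(index_map[len(row_regions):], dtype=np.int64)

    row_pos: dict[int, list[int]] = {}
    for i, rid in enumerate(rows.tolist()):
        row_pos.setdefault(rid, []).append(i)
    col_pos: dict[int, list[int]] = {}
    for j, rid in enumerate(cols.tolist()):
        col_pos.setdefault(rid, []).append(j)

    cell_values: dict[tuple[int, int], list[float]] = {}
    first_anchors = table.first_anchors()
    second_anchors = table.second_anchors()
    for k in range(len(table)):
        ra, rb = first_anchors[k], second_anchors[k]
        ia = rset.index_of(ra) if ra in rset else None
        ib = rset.index_of(rb) if rb in rset else None
        cells: set[tuple[int, int]] = set()
        if ia is not None and ib is not None:
            for i in row_pos.get(ia, ()):
                for j in col_pos.get(ib, ()):
                    cells.add((i, j))
            for i in row_pos.get(ib, ()):
                for j in col_pos.get(ia, ()):
                    cells.add((i, j))
        for cell in cells:
            cell_values.setdefault(cell, []).append(float(values[k]))

    final: dict[tuple[int, int], float] = {}
    for cell, vs in cell_values.items():
        if len(vs) > 1 and combine == "error":
            i, j = cell
            raise ValidationError(
                f"{len(vs)} interactions map to cell ({i}, {j}) = "
                f"({row_regions[i]}, {col_regions[j]}); pass combine='sum' or 'first'"
            )
        final[cell] = sum(vs) if combine == "sum" else vs[0]

    shape = (len(rows), len(cols))
    if backend == "dense":
        grid = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        for (i, j), v in final.items():
            grid[i, j] = v
            mask[i, j] = True
        return ContactMatrix(rset, rows, cols, grid, mask, "dense")
    if any(v == 0 for v in final.values()):
        raise ValidationError(
            "sparse backend cannot store explicit zeros; use the dense backend"
        )
    ii = np.fromiter((c[0] for c in final), dtype=np.int64, count=len(final))
    jj = np.fromiter((c[1] for c in final), dtype=np.int64, count=len(final))
    vv = np.fromiter(final.values(), dtype=float, count=len(final))
    return ContactMatrix(
        rset, rows, cols, sp.coo_matrix((vv, (ii, jj)), shape=shape), None, "sparse"
    )


def deflate(cm: ContactMatrix, value_column: str = "value") -> InteractionTable:
    """Convert non-empty cells back to an interaction table.

    Each non-empty cell (i, j) yields one interaction with anchors
    (row region i, column region j) and the cell value attached as a
    metadata column.  The output is canonically sorted.  Empty cells
    produce nothing; stored zeros (dense backend) are kept as value-0
    interactions.
    """
    mask = cm.filled_mask()
    grid = cm.dense_values()
    ii, jj = np.nonzero(mask)
    row_reg = cm.row_regions()
    col_reg = cm.col_regions()
    table = make_interactions(
        [row_reg[i] for i in ii],
        [col_reg[j] for j in jj],
        metadata=pd.DataFrame({value_column: grid[ii, jj]}),
        chrom_order=cm.region_set.chrom_order,
    )
    sorted_table, _ = canonical_sort(table)
    return sorted_table


def transpose_cm(cm: ContactMatrix) -> ContactMatrix:
    """Swap rows and columns; the value grid is transposed, backend preserved."""
    if cm.backend == "dense":
        return ContactMatrix(
            cm.region_set,
            cm.col_indices,
            cm.row_indices,
            cm.values.T.copy(),
            cm.filled.T.copy(),
            "dense",
        )
    return ContactMatrix(
        cm.region_set, cm.col_indices, cm.row_indices, cm.values.T, None, "sparse"
    )
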