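"""Anchor-indexed tables of pairwise genomic interactions.

An :class:`InteractionTable` stores two parallel vectors of anchor indices
into a shared :class:`~pairspace.regions.RegionSet`, plus per-interaction
metadata columns (a pandas DataFrame) and free-form global metadata.  In
*strict* mode the first anchor index is always <= the second, giving every
interaction a canonical orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import GenomicRegion, RegionSet, ValidationError, build_region_set

__all__ = [
    "InteractionTable",
    "make_interactions",
    "anchors",
    "swap_anchors",
    "concat",
    "canonical_sort",
    "deduplicate",
]


def _as_index_array(seq, n_regions: int, name: str) -> np.ndarray:
    arr = np.asarray(seq, dtype=np.int64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size and (arr.min() < 0 or arr.max() >= n_regions):
        bad = int(np.argmax((arr < 0) | (arr >= n_regions)))
        raise ValidationError(
            f"{name}[{bad}] = {arr[bad]} out of range for a region set of size {n_regions}"
        )
    return arr


@dataclass(frozen=True, eq=False)
class InteractionTable:
    """Pairwise interactions as anchor-index pairs into a region set."""

    region_set: RegionSet
    anchor1: np.ndarray
    anchor2: np.ndarray
    metadata: pd.DataFrame = None  # type: ignore[assignment]
    global_metadata: dict = field(default_factory=dict)
    strict: bool = False

    def __post_init__(self) -> None:
        n_regions = len(self.region_set)
        a1 = _as_index_array(self.anchor1, n_regions, "anchor1")
        a2 = _as_index_array(self.anchor2, n_regions, "anchor2")
        if len(a1) != len(a2):
            raise ValidationError(f"anchor1 ({len(a1)}) and anchor2 ({len(a2)}) differ in length")
        md = self.metadata
        if md is None:
            md = pd.DataFrame(index=pd.RangeIndex(len(a1)))
        if not isinstance(md, pd.DataFrame):
            md = pd.DataFrame(dict(md))
        if len(md) != len(a1):
            raise ValidationError(
                f"metadata has {len(md)} rows for {len(a1)} interactions"
            )
        if self.strict and len(a1) and np.any(a1 > a2):
            bad = int(np.argmax(a1 > a2))
            raise ValidationError(f"strict mode violated at row {bad}: anchor1 > anchor2")
        object.__setattr__(self, "anchor1", a1)
        object.__setattr__(self, "anchor2", a2)
        object.__setattr__(self, "metadata", md.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.anchor1)

    # -- resolved coordinate accessors -------------------------------------
    def first_anchors(self) -> list[GenomicRegion]:
        return [self.region_set[i] for i in self.anchor1]

    def second_anchors(self) -> list[GenomicRegion]:
        return [self.region_set[i] for i in self.anchor2]

    def take(self, rows: Sequence[int]) -> "InteractionTable":
        """Row subset; repeats allowed, order significant."""
        rows = np.asarray(rows, dtype=np.int64)
        if rows.size and (rows.min() < -len(self) or (rows.size and rows.max() >= len(self))):
            raise ValidationError(f"row index out of range for table of {len(self)} rows")
        return InteractionTable(
            self.region_set,
            self.anchor1[rows],
            self.anchor2[rows],
            self.metadata.iloc[rows],
            dict(self.global_metadata),
            self.strict,
        )

    def with_metadata(self, **columns) -> "InteractionTable":
        md = self.metadata.copy()
        for name, values in columns.items():
            md[name] = list(values)
        return InteractionTable(
            self.region_set, self.anchor1, self.anchor2, md, dict(self.global_metadata), self.strict
        )


def make_interactions(
    anchors1: Sequence[GenomicRegion],
    anchors2: Sequence[GenomicRegion],
    metadata: pd.DataFrame | dict | None = None,
    strict: bool = False,
    global_metadata: dict | None = None,
    chrom_order: Sequence[str] | None = None,
) -> InteractionTable:
    """Build an :class:`InteractionTable` from two parallel anchor lists.

    The region set is the sorted, deduplicated union of both lists; stored
    indices resolve back to the inputs exactly.  With ``strict=True`` each
    pair is stored with anchor1 <= anchor2 (swapped where needed).
    """
    anchors1 = list(anchors1)
    anchors2 = list(anchors2)
    if len(anchors1) != len(anchors2):
        raise ValidationError(
            f"anchor lists differ in length: {len(anchors1)} vs {len(anchors2)}"
        )
    rset, index_map = build_region_set(anchors1 + anchors2, chrom_order=chrom_order)
    n = len(anchors1)
    a1 = np.asarray(index_map[:n], dtype=np.int64)
    a2 = np.asarray(index_map[n:], dtype=np.int64)
    if strict:
        a1, a2 = np.minimum(a1, a2), np.maximum(a1, a2)
    return InteractionTable(rset, a1, a2, metadata, global_metadata or {}, strict)


def anchors(table: InteractionTable, which: str = "both"):
    """Resolve anchor indices to coordinates.

    ``which`` is ``"first"``, ``"second"`` or ``"both"`` (a pair of lists).
    """
    if which == "first":
        return table.first_anchors()
    if which == "second":
        return table.second_anchors()
    if which == "both":
        return table.first_anchors(), table.second_anchors()
    raise ValueError(f"which must be 'first', 'second' or 'both', got {which!r}")


def swap_anchors(table: InteractionTable) -> InteractionTable:
    """Canonicalize each row so anchor1 <= anchor2; metadata untouched."""
    a1 = np.minimum(table.anchor1, table.anchor2)
    a2 = np.maximum(table.anchor1, table.anchor2)
    return InteractionTable(
        table.region_set, a1, a2, table.metadata, dict(table.global_metadata), table.strict
    )


def concat(t1: InteractionTable, t2: InteractionTable) -> InteractionTable:
    """Stack two tables row-wise over the deduplicated union of their region sets.

    Metadata column names must match; every row's resolved anchor coordinates
    are preserved exactly.  The result is strict only if both inputs are.
    """
    cols1, cols2 = list(t1.metadata.columns), list(t2.metadata.columns)
    if sorted(map(str, cols1)) != sorted(map(str, cols2)):
        raise ValidationError(
            f"metadata schema mismatch: {cols1} vs {cols2}"
        )
    chrom_order = t1.region_set.chrom_order
    union, index_map = build_region_set(
        list(t1.region_set) + list(t2.region_set), chrom_order=chrom_order
    )
    remap1 = np.asarray(index_map[: len(t1.region_set)], dtype=np.int64)
    remap2 = np.asarray(index_map[len(t1.region_set):], dtype=np.int64)
    a1 = np.concatenate([remap1[t1.anchor1], remap2[t2.anchor1]])
    a2 = np.concatenate([remap1[t1.anchor2], remap2[t2.anchor2]])
    md = pd.concat([t1.metadata, t2.metadata[cols1] if cols1 else t2.metadata], ignore_index=True)
    gm = {**t2.global_metadata, **t1.global_metadata}
    return InteractionTable(union, a1, a2, md, gm, t1.strict and t2.strict)


def canonical_sort(table: InteractionTable) -> tuple[InteractionTable, np.ndarray]:
    """Stable sort by (anchor1 index, anchor2 index).

    Returns the sorted table and the permutation mapping output rows to input
    rows (``perm[k]`` is the input position of output row ``k``).
    """
    perm = np.lexsort((table.anchor2, table.anchor1))
    return table.take(perm), perm


def deduplicate(table: InteractionTable) -> np.ndarray:
    """Flag rows whose stored (anchor1, anchor2) pair already occurred earlier.

    Detection is on stored index pairs as-is; to catch symmetric duplicates,
    apply :func:`swap_anchors` first.
    """
    seen: set[tuple[int, int]] = set()
    flags = np.zeros(len(table), dtype=bool)
    for i, pair in enumerate(zip(table.anchor1.tolist(), table.anchor2.tolist())):
        if pair in seen:
            flags[i] = True
        else:
            seen.add(pair)
    return flags
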