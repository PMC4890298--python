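"""Interaction tables bound to experimental data matrices.

An :class:`AssaySet` couples an interaction table (n rows) with any number
of named n x m value matrices — one row per interaction, one column per
experimental sample — plus per-sample and global metadata.  Typical assays
are read-pair counts or normalized intensities.

:func:`linearize` projects the assay data onto the linear genome around a
fixed bait region, producing a 4C-like per-region track: for every
interaction with exactly one anchor overlapping the bait, the *other*
anchor becomes a track region and the interaction's assay rows are carried
over unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionTable, swap_anchors
from .ops import region_overlap
from .regions import GenomicRegion, ValidationError

__all__ = ["AssaySet", "LinearTrack", "make_assay_set", "subset_assay_set", "linearize"]


def _check_assays(assays: Mapping[str, np.ndarray], n: int) -> tuple[dict[str, np.ndarray], int | None]:
    out: dict[str, np.ndarray] = {}
    m: int | None = None
    for name, mat in assays.items():
        if name in out:
            raise ValidationError(f"duplicate assay name {name!r}")
        arr = np.asarray(mat)
        if arr.ndim != 2 or arr.shape[0] != n:
            raise ValidationError(
                f"assay {name!r} has shape {arr.shape}; expected ({n}, m)"
            )
        if m is None:
            m = arr.shape[1]
        elif arr.shape[1] != m:
            raise ValidationError(
                f"assay {name!r} has {arr.shape[1]} columns; other assays have {m}"
            )
        out[name] = arr
    return out, m


@dataclass(frozen=True, eq=False)
class AssaySet:
    """Interactions plus named interaction x sample data matrices."""

    interactions: InteractionTable
    assays: dict[str, np.ndarray] = field(default_factory=dict)
    sample_metadata: pd.DataFrame = None  # type: ignore[assignment]
    global_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assays, m = _check_assays(self.assays, len(self.interactions))
        smd = self.sample_metadata
        if smd is None:
            smd = pd.DataFrame(index=pd.RangeIndex(0 if m is None else m))
        if not isinstance(smd, pd.DataFrame):
            smd = pd.DataFrame(dict(smd))
        if m is not None and len(smd) != m:
            raise ValidationError(
                f"sample_metadata has {len(smd)} rows for {m} samples"
            )
        object.__setattr__(self, "assays", assays)
        object.__setattr__(self, "sample_metadata", smd.reset_index(drop=True))

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    @property
    def n_samples(self) -> int:
        if self.assays:
            return next(iter(self.assays.values())).shape[1]
        return len(self.sample_metadata)


@dataclass(frozen=True, eq=False)
class LinearTrack:
    """4C-like per-region view of assay data around a bait."""

    regions: tuple[GenomicRegion, ...]
    bait: GenomicRegion
    assays: dict[str, np.ndarray] = field(default_factory=dict)
    sample_metadata: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        assays, m = _check_assays(self.assays, len(self.regions))
        smd = self.sample_metadata
        if smd is None:
            smd = pd.DataFrame(index=pd.RangeIndex(0 if m is None else m))
        object.__setattr__(self, "assays", assays)
        object.__setattr__(self, "sample_metadata", smd.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.regions)


def make_assay_set(
    interactions: InteractionTable,
    assays: Mapping[str, np.ndarray] | None = None,
    sample_metadata: pd.DataFrame | dict | None = None,
    global_metadata: dict | None = None,
) -> AssaySet:
    """Construct a validated :class:`AssaySet` (dimension-checked)."""
    return AssaySet(interactions, dict(assays or {}), sample_metadata, global_metadata or {})


def subset_assay_set(
    aset: AssaySet, row_indices: Sequence[int], col_indices: Sequence[int]
) -> AssaySet:
    """Subset interactions by rows and samples by columns; repeats allowed."""
    rows = np.asarray(row_indices, dtype=np.int64)
    cols = np.asarray(col_indices, dtype=np.int64)
    n, m = aset.n_interactions, aset.n_samples
    if rows.size and (rows.min() < 0 or rows.max() >= n):
        raise ValidationError(f"row index out of range for {n} interactions")
    if cols.size and (cols.min() < 0 or cols.max() >= m):
        raise ValidationError(f"column index out of range for {m} samples")
    return AssaySet(
        aset.interactions.take(rows),
        {name: mat[np.ix_(rows, cols)] for name, mat in aset.assays.items()},
        aset.sample_metadata.iloc[cols],
        dict(aset.global_metadata),
    )


def linearize(
    aset: AssaySet,
    bait: GenomicRegion,
    keep_double: bool = False,
    maxgap: int = 0,
    minoverlap: int = 1,
) -> LinearTrack:
    """Project interactions touching a bait onto the linear genome.

    Rows of the output are, in input order, the interactions for which
    exactly one anchor overlaps the bait; the reported region is the
    non-overlapping anchor and the assay rows are carried over unchanged
    (no aggregation; distinct interactions may report the same region).
    Interactions whose *both* anchors overlap the bait are dropped by
    default — the extraction rule would have to invent a signal region for
    them — or, with ``keep_double=True``, kept and reported at their
    canonical slot-1 anchor.
    """
    if not isinstance(bait, GenomicRegion):
        raise ValidationError(f"bait must be a GenomicRegion, got {type(bait).__name__}")
    first = aset.interactions.first_anchors()
    second = aset.interactions.second_anchors()
    canon_first = swap_anchors(aset.interactions).first_anchors()
    rows: list[int] = []
    regions: list[GenomicRegion] = []
    for i in range(len(aset.interactions)):
        h1 = region_overlap(first[i], bait, maxgap, minoverlap)
        h2 = region_overlap(second[i], bait, maxgap, minoverlap)
        if h1 and h2:
            if keep_double:
                rows.append(i)
                regions.append(canon_first[i])
        elif h1:
            rows.append(i)
            regions.append(second[i])
        elif h2:
            rows.append(i)
            regions.append(first[i])
    idx = np.asarray(rows, dtype=np.int64)
    return LinearTrack(
        tuple(regions),
        bait,
        {name: mat[idx] for name, mat in aset.assays.items()},
        aset.sample_metadata,
    )
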