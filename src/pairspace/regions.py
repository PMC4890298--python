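"""Genomic regions and the deduplicated reference region set.

Coordinates are 0-based half-open throughout (BEDPE/BED native).  A
:class:`RegionSet` is the single coordinate store for a table of pairwise
interactions: every anchor is an integer index into it, so each distinct
region is stored exactly once no matter how many interactions use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = ["GenomicRegion", "RegionSet", "build_region_set", "ValidationError"]

_STRANDS = ("+", "-", ".")
_STRAND_RANK = {s: i for i, s in enumerate(_STRANDS)}


class ValidationError(ValueError):
    """Raised when a region, table or matrix violates a structural invariant."""


@dataclass(frozen=True, order=False)
class GenomicRegion:
    """One genomic interval: chromosome, half-open [start, end), optional strand.

    Zero-width regions are rejected: with half-open coordinates they contain
    no bases and make overlap semantics ambiguous.  Strand is stored but is
    ignored by every overlap and distance operation.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.chrom, str) or not self.chrom:
            raise ValidationError(f"chromosome name must be a non-empty string, got {self.chrom!r}")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValidationError(f"coordinates must be integers, got {self.start!r}..{self.end!r}")
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} in {self.chrom}")
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end (zero-width regions rejected): {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Half-open midpoint (start + end) / 2; may be half-integral."""
        return (self.start + self.end) / 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _sort_key(region: GenomicRegion, chrom_rank: dict | None):
    if chrom_rank is None:
        chrom_key: object = region.chrom
    else:
        try:
            chrom_key = chrom_rank[region.chrom]
        except KeyError:
            raise ValidationError(
                f"chromosome {region.chrom!r} not in the supplied chromosome order"
            ) from None
    return (chrom_key, region.start, region.end, _STRAND_RANK[region.strand])


@dataclass(frozen=True)
class RegionSet:
    """Strictly sorted, deduplicated reference list of :class:`GenomicRegion`.

    The canonical order is chromosome (lexicographic by default, or an
    explicit ``chrom_order`` supplied at construction), then start, then end,
    then strand in the order ``+ - .``.  Use :func:`build_region_set` to
    construct one from arbitrary input regions.
    """

    regions: tuple[GenomicRegion, ...]
    chrom_order: tuple[str, ...] | None = None
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        rank = None if self.chrom_order is None else {c: i for i, c in enumerate(self.chrom_order)}
        keys = [_sort_key(r, rank) for r in self.regions]
        for i in range(1, len(keys)):
            if keys[i - 1] >= keys[i]:
                raise ValidationError(
                    f"region set not strictly sorted/deduplicated at position {i}: "
                    f"{self.regions[i - 1]} !< {self.regions[i]}"
                )
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(self.regions)})

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def index_of(self, region: GenomicRegion) -> int:
        """Exact-identity (coordinates + strand) lookup; KeyError if absent."""
        return self._index[region]

    def __contains__(self, region: GenomicRegion) -> bool:
        return region in self._index


def build_region_set(
    regions: Iterable[GenomicRegion],
    chrom_order: Sequence[str] | None = None,
) -> tuple[RegionSet, list[int]]:
    """Sort and deduplicate ``regions`` into a :class:`RegionSet`.

    Returns the set together with an ``index_map`` of the input's length such
    that ``region_set[index_map[i]] == regions[i]``.  The output is invariant
    under permutation of the input (the map permutes accordingly).

    Parameters
    ----------
    regions
        Input regions; validated on construction of each :class:`GenomicRegion`.
    chrom_order
        Optional explicit chromosome order governing all sorting; default is
        lexicographic by name.
    """
    regions = list(regions)
    for pos, r in enumerate(regions):
        if not isinstance(r, GenomicRegion):
            raise ValidationError(f"input position {pos}: expected GenomicRegion, got {type(r).__name__}")
    rank = None if chrom_order is None else {c: i for i, c in enumerate(chrom_order)}
    uniq = sorted(set(regions), key=lambda r: _sort_key(r, rank))
    rset = RegionSet(tuple(uniq), None if chrom_order is None else tuple(chrom_order))
    index_map = [rset.index_of(r) for r in regions]
    return rset, index_map
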