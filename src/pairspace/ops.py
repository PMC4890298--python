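"""Geometric and overlap methods on interaction tables.

Implements the 1D/2D overlap semantics for pairwise interactions: an
interaction overlaps a single interval (1D) if *either* anchor overlaps it,
and overlaps a pair of intervals (2D) if one anchor overlaps one interval
and the other anchor overlaps the other, trying both assignments.  Also
provides region linking, anchor distances and minimum bounding boxes in the
interaction space.

All operations ignore strand.  Subject lookups use per-chromosome interval
trees internally with an exact predicate post-filter; the trees are an
engine detail, not part of the API.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Hashable, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

from .interactions import InteractionTable, swap_anchors
from .regions import GenomicRegion, ValidationError

__all__ = [
    "OverlapHit",
    "LinkedTriplet",
    "BoundingBox",
    "region_overlap",
    "overlaps_any_region",
    "overlaps_pair",
    "overlaps_interactions",
    "link_overlaps",
    "pair_distance",
    "is_intra",
    "bounding_box",
]

DISTANCE_MODES = ("mid", "gap", "span")


class OverlapHit(NamedTuple):
    query_index: int
    subject_index: int


class LinkedTriplet(NamedTuple):
    interaction_index: int
    subject1_index: int
    subject2_index: int


@dataclass(frozen=True)
class BoundingBox:
    """Minimum bounding box of a group of interactions in interaction space."""

    group_id: Hashable
    box1: GenomicRegion
    box2: GenomicRegion
    n_members: int


def region_overlap(
    a: GenomicRegion, b: GenomicRegion, maxgap: int = 0, minoverlap: int = 1
) -> bool:
    """Overlap predicate underlying every higher-level overlap method.

    True iff the regions share a chromosome and either their intersection is
    at least ``minoverlap`` bases, or ``minoverlap`` is 1 and the gap between
    them is at most ``maxgap``.  Abutting half-open intervals have gap 0, so
    they overlap under the defaults (maxgap=0, minoverlap=1).
    """
    if maxgap < 0 or minoverlap < 1:
        raise ValueError("require maxgap >= 0 and minoverlap >= 1")
    if a.chrom != b.chrom:
        return False
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter >= minoverlap:
        return True
    return minoverlap == 1 and -inter <= maxgap


class _SubjectIndex:
    """Per-chromosome interval trees over a list of subject regions."""

    def __init__(self, subjects: Sequence[GenomicRegion], maxgap: int, minoverlap: int):
        self.subjects = list(subjects)
        self.maxgap = maxgap
        self.minoverlap = minoverlap
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for j, s in enumerate(self.subjects):
            trees[s.chrom].addi(s.start, s.end, j)
        self._trees = dict(trees)
        # Pad queries so gap-within-maxgap candidates reach the tree; the
        # exact predicate then filters.
        self._pad = maxgap + 1

    def hits(self, region: GenomicRegion) -> list[int]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        lo = max(0, region.start - self._pad)
        out = [
            iv.data
            for iv in tree.overlap(lo, region.end + self._pad)
            if region_overlap(region, self.subjects[iv.data], self.maxgap, self.minoverlap)
        ]
        out.sort()
        return out


def overlaps_any_region(
    table: InteractionTable,
    subjects: Sequence[GenomicRegion],
    maxgap: int = 0,
    minoverlap: int = 1,
) -> list[OverlapHit]:
    """1D overlaps: hit (i, j) iff either anchor of interaction i overlaps subject j.

    Hits are sorted by (query, subject) and deduplicated when both anchors
    hit the same subject.
    """
    index = _SubjectIndex(subjects, maxgap, minoverlap)
    first = table.first_anchors()
    second = table.second_anchors()
    out: list[OverlapHit] = []
    for i in range(len(table)):
        js = set(index.hits(first[i])) | set(index.hits(second[i]))
        out.extend(OverlapHit(i, j) for j in sorted(js))
    return out


def overlaps_pair(
    table: InteractionTable,
    region_a: GenomicRegion,
    region_b: GenomicRegion,
    maxgap: int = 0,
    minoverlap: int = 1,
) -> np.ndarray:
    """2D overlap with a pair of intervals, one anchor on each, either way round."""
    out = np.zeros(len(table), dtype=bool)
    first = table.first_anchors()
    second = table.second_anchors()
    for i in range(len(table)):
        a1, a2 = first[i], second[i]
        out[i] = (
            region_overlap(a1, region_a, maxgap, minoverlap)
            and region_overlap(a2, region_b, maxgap, minoverlap)
        ) or (
            region_overlap(a1, region_b, maxgap, minoverlap)
            and region_overlap(a2, region_a, maxgap, minoverlap)
        )
    return out


def _region_overlap_matrix(
    rs1, rs2, maxgap: int, minoverlap: int
) -> np.ndarray:
    """Boolean |rs1| x |rs2| matrix of region-level overlaps."""
    index = _SubjectIndex(list(rs2), maxgap, minoverlap)
    mat = np.zeros((len(rs1), len(rs2)), dtype=bool)
    for p, r in enumerate(rs1):
        mat[p, index.hits(r)] = True
    return mat


def overlaps_interactions(
    t1: InteractionTable,
    t2: InteractionTable,
    maxgap: int = 0,
    minoverlap: int = 1,
    match_slots: bool = False,
) -> list[OverlapHit]:
    """2D overlap between two interaction tables.

    Hit (i, j) iff t1's anchors overlap t2's anchors pairwise.  By default
    either anchor pairing is accepted (first-with-first or first-with-second);
    ``match_slots=True`` requires same-slot matching only.
    """
    if len(t1) == 0 or len(t2) == 0:
        return []
    mat = _region_overlap_matrix(t1.region_set, t2.region_set, maxgap, minoverlap)
    m11 = mat[np.ix_(t1.anchor1, t2.anchor1)]
    m22 = mat[np.ix_(t1.anchor2, t2.anchor2)]
    hit = m11 & m22
    if not match_slots:
        m12 = mat[np.ix_(t1.anchor1, t2.anchor2)]
        m21 = mat[np.ix_(t1.anchor2, t2.anchor1)]
        hit |= m12 & m21
    qi, sj = np.nonzero(hit)
    return [OverlapHit(int(i), int(j)) for i, j in zip(qi, sj)]


def link_overlaps(
    table: InteractionTable,
    subjects1: Sequence[GenomicRegion],
    subjects2: Sequence[GenomicRegion] | None = None,
    maxgap: int = 0,
    minoverlap: int = 1,
) -> list[LinkedTriplet]:
    """Find interactions linking a region in one subject set to a region in another.

    Two-set mode emits (i, p, q) whenever one anchor of interaction i
    overlaps ``subjects1[p]`` and the other overlaps ``subjects2[q]``, trying
    both anchor assignments.  Single-set mode (``subjects2`` omitted) links
    the set against itself, canonicalizes each triplet to ``p <= q`` and
    deduplicates; self-pairs (p == q) are kept.  Output is sorted by
    (interaction, subject1, subject2).
    """
    single = subjects2 is None
    s2 = subjects1 if single else subjects2
    idx1 = _SubjectIndex(subjects1, maxgap, minoverlap)
    idx2 = idx1 if single else _SubjectIndex(s2, maxgap, minoverlap)
    first = table.first_anchors()
    second = table.second_anchors()
    out: list[LinkedTriplet] = []
    for i in range(len(table)):
        a1, a2 = first[i], second[i]
        pairs = {
            (p, q)
            for p in idx1.hits(a1)
            for q in idx2.hits(a2)
        } | {
            (p, q)
            for p in idx1.hits(a2)
            for q in idx2.hits(a1)
        }
        if single:
            pairs = {(min(p, q), max(p, q)) for p, q in pairs}
        out.extend(LinkedTriplet(i, p, q) for p, q in sorted(pairs))
    return out


def is_intra(table: InteractionTable) -> np.ndarray:
    """True per interaction iff both anchors share a chromosome (cis)."""
    out = np.zeros(len(table), dtype=bool)
    for i, (a, b) in enumerate(zip(table.first_anchors(), table.second_anchors())):
        out[i] = a.chrom == b.chrom
    return out


def pair_distance(table: InteractionTable, mode: str = "mid") -> np.ndarray:
    """Distance between the two anchors on the linear genome, per interaction.

    With L the anchor with the smaller start and R the other (same
    chromosome):

    - ``mid``:  |midpoint(R) - midpoint(L)|, midpoints half-open (start+end)/2
      and possibly half-integral;
    - ``gap``:  max(0, R.start - L.end), the clamped inter-anchor gap;
    - ``span``: max(end) - min(start), the total footprint.

    Trans (inter-chromosomal) interactions yield NaN in every mode.
    """
    if mode not in DISTANCE_MODES:
        raise ValueError(f"mode must be one of {DISTANCE_MODES}, got {mode!r}")
    out = np.full(len(table), np.nan)
    for i, (a, b) in enumerate(zip(table.first_anchors(), table.second_anchors())):
        if a.chrom != b.chrom:
            continue
        left, right = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
        if mode == "mid":
            out[i] = abs(right.midpoint - left.midpoint)
        elif mode == "gap":
            out[i] = max(0, right.start - left.end)
        else:
            out[i] = max(a.end, b.end) - min(a.start, b.start)
    return out


def bounding_box(
    table: InteractionTable, grouping: Sequence[Hashable]
) -> list[BoundingBox]:
    """Minimum bounding box per group of interactions in the interaction space.

    Rows are first canonicalized (swap_anchors) so slot membership is well
    defined; within each group, all slot-1 anchors must share one chromosome
    and all slot-2 anchors another (possibly the same).  Groups appear in
    order of first occurrence.
    """
    grouping = list(grouping)
    if len(grouping) != len(table):
        raise ValidationError(
            f"grouping has {len(grouping)} labels for {len(table)} interactions"
        )
    canon = swap_anchors(table)
    first = canon.first_anchors()
    second = canon.second_anchors()
    members: dict[Hashable, list[int]] = {}
    for i, g in enumerate(grouping):
        members.setdefault(g, []).append(i)
    out: list[BoundingBox] = []
    for g, rows in members.items():
        boxes = []
        for slot_regions in (first, second):
            regs = [slot_regions[i] for i in rows]
            chroms = {r.chrom for r in regs}
            if len(chroms) > 1:
                raise ValidationError(
                    f"group {g!r} mixes chromosomes {sorted(chroms)} within one anchor slot"
                )
            boxes.append(
                GenomicRegion(
                    regs[0].chrom,
                    min(r.start for r in regs),
                    max(r.end for r in regs),
                )
            )
        out.append(BoundingBox(g, boxes[0], boxes[1], len(rows)))
    return out
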