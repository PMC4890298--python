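"""Exhaustive brute-force oracles, independent of the library internals.

Everything here works by direct enumeration — base-by-base set arithmetic
for the overlap predicate, all-pairs loops over every query/subject
combination, and comparison sorts — so it is slow but transparently
correct on the small fixtures the tests use (coordinates up to a few
thousand bases).
"""

from __future__ import annotations

from pairspace import GenomicRegion, InteractionTable


def brute_overlap(a: GenomicRegion, b: GenomicRegion, maxgap: int = 0, minoverlap: int = 1) -> bool:
    """Base-by-base overlap/gap predicate."""
    if a.chrom != b.chrom:
        return False
    bases_a = set(range(a.start, a.end))
    bases_b = set(range(b.start, b.end))
    shared = bases_a & bases_b
    if len(shared) >= minoverlap:
        return True
    if minoverlap != 1 or shared:
        return False
    between = set(range(min(a.end, b.end), max(a.start, b.start))) - bases_a - bases_b
    return len(between) <= maxgap


def brute_any(table: InteractionTable, subjects, maxgap=0, minoverlap=1):
    first, second = table.first_anchors(), table.second_anchors()
    return [
        (i, j)
        for i in range(len(table))
        for j, s in enumerate(subjects)
        if brute_overlap(first[i], s, maxgap, minoverlap)
        or brute_overlap(second[i], s, maxgap, minoverlap)
    ]


def brute_pair(table: InteractionTable, ra, rb, maxgap=0, minoverlap=1):
    first, second = table.first_anchors(), table.second_anchors()
    out = []
    for a1, a2 in zip(first, second):
        out.append(
            (brute_overlap(a1, ra, maxgap, minoverlap) and brute_overlap(a2, rb, maxgap, minoverlap))
            or (brute_overlap(a1, rb, maxgap, minoverlap) and brute_overlap(a2, ra, maxgap, minoverlap))
        )
    return out


def brute_interactions(t1: InteractionTable, t2: InteractionTable, maxgap=0, minoverlap=1,
                       match_slots: bool = False):
    f1, s1 = t1.first_anchors(), t1.second_anchors()
    f2, s2 = t2.first_anchors(), t2.second_anchors()
    hits = []
    for i in range(len(t1)):
        for j in range(len(t2)):
            same = brute_overlap(f1[i], f2[j], maxgap, minoverlap) and brute_overlap(
                s1[i], s2[j], maxgap, minoverlap
            )
            cross = brute_overlap(f1[i], s2[j], maxgap, minoverlap) and brute_overlap(
                s1[i], f2[j], maxgap, minoverlap
            )
            if same or (cross and not match_slots):
                hits.append((i, j))
    return hits


def brute_link(table: InteractionTable, subjects1, subjects2=None, maxgap=0, minoverlap=1):
    single = subjects2 is None
    s2 = subjects1 if single else subjects2
    first, second = table.first_anchors(), table.second_anchors()
    out = []
    for i in range(len(table)):
        pairs = set()
        for p, rp in enumerate(subjects1):
            for q, rq in enumerate(s2):
                if (
                    brute_overlap(first[i], rp, maxgap, minoverlap)
                    and brute_overlap(second[i], rq, maxgap, minoverlap)
                ) or (
                    brute_overlap(second[i], rp, maxgap, minoverlap)
                    and brute_overlap(first[i], rq, maxgap, minoverlap)
                ):
                    pairs.add((min(p, q), max(p, q)) if single else (p, q))
        out.extend((i, p, q) for p, q in sorted(pairs))
    return out


def brute_linearize_rows(table: InteractionTable, bait: GenomicRegion, keep_double: bool = False):
    """(row index, reported region) pairs per the bait-extraction rule."""
    first, second = table.first_anchors(), table.second_anchors()
    out = []
    for i in range(len(table)):
        h1 = brute_overlap(first[i], bait)
        h2 = brute_overlap(second[i], bait)
        if h1 and h2:
            if keep_double:
                lo = min(first[i], second[i], key=lambda r: (r.chrom, r.start, r.end, r.strand))
                out.append((i, lo))
        elif h1:
            out.append((i, second[i]))
        elif h2:
            out.append((i, first[i]))
    return out


def brute_sort_rows(pairs):
    """Stable comparison sort of (anchor1, anchor2) index pairs.

    Returns the permutation (output position -> input position) produced by
    an explicit insertion sort, for checking canonical_sort.
    """
    order = list(range(len(pairs)))
    for i in range(1, len(order)):
        j = i
        while j > 0 and pairs[order[j - 1]] > pairs[order[j]]:
            order[j - 1], order[j] = order[j], order[j - 1]
            j -= 1
    return order
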