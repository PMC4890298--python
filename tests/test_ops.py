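"""Overlap, linking, distance and bounding-box methods vs brute-force oracles."""

import numpy as np
import pytest

from pairspace import (
    GenomicRegion,
    ValidationError,
    bounding_box,
    is_intra,
    link_overlaps,
    make_interactions,
    overlaps_any_region,
    overlaps_interactions,
    overlaps_pair,
    pair_distance,
    region_overlap,
    swap_anchors,
)

from .brute import brute_any, brute_interactions, brute_link, brute_overlap, brute_pair
from .conftest import random_regions, random_table

R = GenomicRegion


class TestRegionOverlap:
    @pytest.mark.parametrize(
        "a, b, kwargs, expected",
        [
            (R("chr1", 100, 200), R("chr1", 150, 160), {}, True),  # containment
            (R("chr1", 100, 200), R("chr1", 200, 300), {}, True),  # abutting, gap 0
            (R("chr1", 100, 200), R("chr1", 210, 220), {"maxgap": 9}, False),  # gap 10
            (R("chr1", 100, 200), R("chr1", 210, 220), {"maxgap": 10}, True),
            (R("chr1", 100, 200), R("chr2", 100, 200), {"maxgap": 10**6}, False),  # trans
            (R("chr1", 100, 200), R("chr1", 150, 260), {"minoverlap": 50}, True),
            (R("chr1", 100, 200), R("chr1", 150, 260), {"minoverlap": 51}, False),
            # minoverlap > 1 disables the gap rule entirely
            (R("chr1", 100, 200), R("chr1", 200, 300), {"minoverlap": 2, "maxgap": 100}, False),
        ],
    )
    def test_predicate_cases(self, a, b, kwargs, expected):
        assert region_overlap(a, b, **kwargs) is expected
        assert brute_overlap(a, b, **kwargs) is expected

    def test_matches_bruteforce_scan(self, rng):
        """Random pairs against the base-by-base enumeration oracle."""
        for _ in range(300):
            a, b = random_regions(rng, 2, max_coord=300, max_width=40)
            maxgap = int(rng.integers(0, 20))
            minoverlap = int(rng.integers(1, 10))
            assert region_overlap(a, b, maxgap, minoverlap) == brute_overlap(
                a, b, maxgap, minoverlap
            ), (a, b, maxgap, minoverlap)

    def test_strand_is_ignored(self):
        assert region_overlap(R("chr1", 0, 10, "+"), R("chr1", 5, 15, "-"))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            region_overlap(R("chr1", 0, 10), R("chr1", 0, 10), maxgap=-1)
        with pytest.raises(ValueError):
            region_overlap(R("chr1", 0, 10), R("chr1", 0, 10), minoverlap=0)


class TestOverlapsAnyRegion:
    def test_second_anchor_hit_and_miss(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        assert overlaps_any_region(t, [R("chr1", 550, 560)]) == [(0, 0)]
        assert overlaps_any_region(t, [R("chr1", 250, 300)]) == []

    def test_both_anchors_hitting_same_subject_reported_once(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        assert overlaps_any_region(t, [R("chr1", 0, 1000)]) == [(0, 0)]

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            t = random_table(rng, 50)
            subjects = random_regions(rng, 20)
            maxgap = int(rng.integers(0, 15))
            assert overlaps_any_region(t, subjects, maxgap) == brute_any(t, subjects, maxgap)


class TestOverlapsPair:
    def test_assignment_symmetry(self):
        gene, enhancer = R("chr1", 150, 160), R("chr1", 550, 560)
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        assert overlaps_pair(t, gene, enhancer).tolist() == [True]
        assert overlaps_pair(t, enhancer, gene).tolist() == [True]

    def test_one_dimensional_hit_is_not_enough(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        assert overlaps_pair(t, R("chr1", 150, 160), R("chr1", 900, 950)).tolist() == [False]

    def test_inter_chromosomal_pair(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr2", 500, 600)])
        assert overlaps_pair(t, R("chr2", 550, 560), R("chr1", 150, 160)).tolist() == [True]

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            t = random_table(rng, 50)
            ra, rb = random_regions(rng, 2)
            assert overlaps_pair(t, ra, rb).tolist() == brute_pair(t, ra, rb)
            assert overlaps_pair(t, ra, rb).tolist() == overlaps_pair(t, rb, ra).tolist()


class TestOverlapsInteractions:
    def test_identity_and_swapped(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        swapped = make_interactions([R("chr1", 500, 600)], [R("chr1", 100, 200)])
        assert overlaps_interactions(t, t) == [(0, 0)]
        assert overlaps_interactions(t, swapped) == [(0, 0)]
        assert overlaps_interactions(t, swapped, match_slots=True) == []

    def test_single_slot_overlap_is_not_a_hit(self):
        t1 = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        t2 = make_interactions([R("chr1", 150, 250)], [R("chr2", 0, 100)])
        assert overlaps_interactions(t1, t2) == []

    def test_matches_bruteforce_and_transpose_symmetry(self, rng):
        for _ in range(5):
            t1 = random_table(rng, 30)
            t2 = random_table(rng, 25)
            hits = overlaps_interactions(t1, t2)
            assert hits == brute_interactions(t1, t2)
            assert sorted((j, i) for i, j in hits) == [
                tuple(h) for h in overlaps_interactions(t2, t1)
            ]
            assert overlaps_interactions(t1, t2, match_slots=True) == brute_interactions(
                t1, t2, match_slots=True
            )


class TestLinkOverlaps:
    def test_two_set_mode(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        genes, enhancers = [R("chr1", 150, 160)], [R("chr1", 550, 560)]
        assert link_overlaps(t, genes, enhancers) == [(0, 0, 0)]

    def test_single_set_canonical_order(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        assert link_overlaps(t, [R("chr1", 150, 160), R("chr1", 550, 560)]) == [(0, 0, 1)]

    def test_no_hits(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 500, 600)])
        assert link_overlaps(t, [R("chr2", 0, 100)]) == []

    def test_single_set_keeps_self_pairs(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 150, 250)])
        assert link_overlaps(t, [R("chr1", 0, 1000)]) == [(0, 0, 0)]

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            t = random_table(rng, 30)
            s1 = random_regions(rng, 12)
            s2 = random_regions(rng, 8)
            assert link_overlaps(t, s1, s2) == brute_link(t, s1, s2)
            assert link_overlaps(t, s1) == brute_link(t, s1)


class TestPairDistance:
    def test_worked_example(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr1", 300, 400)])
        assert pair_distance(t, "mid").tolist() == [200.0]
        assert pair_distance(t, "gap").tolist() == [100.0]
        assert pair_distance(t, "span").tolist() == [300.0]

    def test_overlapping_anchors_gap_clamped_to_zero(self):
        t = make_interactions([R("chr1", 100, 300)], [R("chr1", 200, 400)])
        assert pair_distance(t, "gap").tolist() == [0.0]

    def test_trans_pairs_are_missing_in_every_mode(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr2", 100, 200)])
        for mode in ("mid", "gap", "span"):
            assert np.isnan(pair_distance(t, mode)).all()

    def test_half_integral_midpoint_distance(self):
        t = make_interactions([R("chr1", 0, 10)], [R("chr1", 20, 31)])
        assert pair_distance(t, "mid").tolist() == [20.5]

    def test_unknown_mode(self, rng):
        with pytest.raises(ValueError):
            pair_distance(random_table(rng, 1), "euclid")

    def test_direct_arithmetic_and_span_identity(self, rng):
        """span = gap + width1 + width2 for disjoint cis pairs; all modes match arithmetic."""
        for _ in range(1000):
            a, b = random_regions(rng, 2, chroms=("chr1", "chr2"), max_coord=5000)
            t = make_interactions([a], [b])
            mid = pair_distance(t, "mid")[0]
            gap = pair_distance(t, "gap")[0]
            span = pair_distance(t, "span")[0]
            if a.chrom != b.chrom:
                assert np.isnan(mid) and np.isnan(gap) and np.isnan(span)
                continue
            left, right = sorted([a, b], key=lambda r: (r.start, r.end))
            assert mid == abs((right.start + right.end) / 2 - (left.start + left.end) / 2)
            assert gap == max(0, right.start - left.end)
            assert span == max(a.end, b.end) - min(a.start, b.start)
            if gap > 0:
                assert span == gap + a.width + b.width

    def test_invariant_under_anchor_swap(self, rng):
        t = random_table(rng, 40)
        s = swap_anchors(t)
        for mode in ("mid", "gap", "span"):
            np.testing.assert_array_equal(pair_distance(t, mode), pair_distance(s, mode))


class TestIsIntra:
    def test_cis_trans_and_empty(self):
        t = make_interactions(
            [R("chr1", 0, 10), R("chr1", 0, 10)], [R("chr1", 50, 60), R("chr2", 50, 60)]
        )
        assert is_intra(t).tolist() == [True, False]
        assert is_intra(make_interactions([], [])).tolist() == []


class TestBoundingBox:
    def test_worked_example(self):
        t = make_interactions(
            [R("chr1", 100, 200), R("chr1", 150, 250)],
            [R("chr2", 300, 400), R("chr2", 100, 150)],
        )
        (box,) = bounding_box(t, ["g", "g"])
        assert box.box1 == R("chr1", 100, 250)
        assert box.box2 == R("chr2", 100, 400)
        assert box.n_members == 2

    def test_singleton_group_is_its_own_box(self):
        t = make_interactions([R("chr1", 100, 200)], [R("chr2", 300, 400)])
        (box,) = bounding_box(t, ["solo"])
        assert box.box1 == R("chr1", 100, 200) and box.box2 == R("chr2", 300, 400)

    def test_mixed_chromosomes_in_slot_rejected(self):
        t = make_interactions(
            [R("chr1", 0, 10), R("chr2", 0, 10)], [R("chr2", 50, 60), R("chr2", 70, 80)]
        )
        with pytest.raises(ValidationError, match="bad_group"):
            bounding_box(t, ["bad_group", "bad_group"])

    def test_minimality_on_random_groups(self, rng):
        """Boxes contain every member anchor and cannot shrink by 1 bp."""
        n_groups = 0
        while n_groups < 100:
            k = int(rng.integers(1, 8))
            chrom_a = str(rng.choice(["chr1", "chr2"]))
            chrom_b = str(rng.choice(["chr1", "chr2"]))
            a = random_regions(rng, k, chroms=(chrom_a,))
            b = random_regions(rng, k, chroms=(chrom_b,))
            t = make_interactions(a, b)
            (box,) = bounding_box(t, ["g"] * k)
            canon = swap_anchors(t)
            for slot_box, regs in ((box.box1, canon.first_anchors()), (box.box2, canon.second_anchors())):
                assert all(
                    r.chrom == slot_box.chrom and r.start >= slot_box.start and r.end <= slot_box.end
                    for r in regs
                )
                # 1 bp shrink on either edge excludes at least one member
                assert min(r.start for r in regs) == slot_box.start
                assert max(r.end for r in regs) == slot_box.end
            n_groups += 1

    def test_overlap_results_invariant_under_anchor_swap(self, rng):
        t = random_table(rng, 40)
        s = swap_anchors(t)
        subjects = random_regions(rng, 15)
        assert overlaps_any_region(t, subjects) == overlaps_any_region(s, subjects)
        assert link_overlaps(t, subjects) == link_overlaps(s, subjects)
        ra, rb = random_regions(rng, 2)
        assert overlaps_pair(t, ra, rb).tolist() == overlaps_pair(s, ra, rb).tolist()
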