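"""Shared fixtures: seeded random region/table generators on a small genome.

Coordinates are kept small (a few kb) so the base-by-base brute-force
oracles in ``tests.brute`` stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pairspace import GenomicRegion, make_interactions

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

CHROMS = ("chr1", "chr2", "chr10")


def random_region(rng: np.random.Generator, chroms=CHROMS, max_coord=2000, max_width=100) -> GenomicRegion:
    start = int(rng.integers(0, max_coord))
    width = int(rng.integers(1, max_width + 1))
    strand = str(rng.choice(["+", "-", "."]))
    return GenomicRegion(str(chroms[rng.integers(0, len(chroms))]), start, start + width, strand)


def random_regions(rng, n, **kw):
    return [random_region(rng, **kw) for _ in range(n)]


def random_table(rng: np.random.Generator, n: int, strict: bool = False, **kw):
    return make_interactions(random_regions(rng, n, **kw), random_regions(rng, n, **kw), strict=strict)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def worked_fixture():
    """Three interactions and a chr1:0-1000 bait: the standard linearize demo.

    One anchor of I1 and of I2 falls in the bait; I3 avoids it entirely.
    """
    import pandas as pd

    from pairspace import make_assay_set

    table = make_interactions(
        [
            GenomicRegion("chr1", 100, 200),
            GenomicRegion("chr1", 300, 400),
            GenomicRegion("chr2", 0, 50),
        ],
        [
            GenomicRegion("chr2", 50, 100),
            GenomicRegion("chr1", 5000, 6000),
            GenomicRegion("chr2", 500, 600),
        ],
    )
    counts = np.array([[5, 2], [1, 0], [7, 7]])
    aset = make_assay_set(table, {"counts": counts}, pd.DataFrame({"sample": ["a", "b"]}))
    return aset, GenomicRegion("chr1", 0, 1000)
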