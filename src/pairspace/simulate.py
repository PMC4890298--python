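"""Deterministic synthetic interaction data for testing and demos.

Everything here is driven by a single integer seed through one explicit
``numpy.random.Generator`` stream — no global randomness — so identical
calls produce byte-identical objects on any platform.

The generator emulates the gross shape of Hi-C-like pair data: fixed-width
anchors placed uniformly on a small genome, a tunable cis (same-chromosome)
fraction, and read-pair counts whose mean decays with genomic distance for
cis pairs, mimicking the distance-dependent contact trend.  It does *not*
emulate TADs, compartments or restriction-fragment structure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import AssaySet, make_assay_set
from .interactions import make_interactions
from .regions import GenomicRegion, ValidationError

__all__ = [
    "parse_genome_spec",
    "tile_genome",
    "simulate_interaction_data",
    "DEFAULT_GENOME",
]

# Two-chromosome toy genome used by the CLI and the worked examples.
DEFAULT_GENOME: dict[str, int] = {"chr1": 1_000_000, "chr2": 800_000}


def parse_genome_spec(text: str) -> dict[str, int]:
    """Parse ``"chr1:1000000,chr2:800000"`` into a chromosome-length mapping."""
    genome: dict[str, int] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        name, _, length = part.rpartition(":")
        if not name:
            raise ValidationError(f"malformed genome spec entry {part!r}; expected name:length")
        genome[name] = int(length)
    _validate_genome(genome)
    return genome


def _validate_genome(genome: Mapping[str, int]) -> None:
    if not genome:
        raise ValidationError("genome spec is empty")
    for name, length in genome.items():
        if length <= 0:
            raise ValidationError(f"chromosome {name!r} has non-positive length {length}")


def tile_genome(genome: Mapping[str, int], bin_width: int) -> list[GenomicRegion]:
    """Tile every chromosome into consecutive half-open bins of ``bin_width``.

    The last bin of each chromosome is truncated at the chromosome end.
    Output is in canonical order (chromosomes lexicographic, then start).
    """
    _validate_genome(genome)
    if bin_width < 1:
        raise ValidationError(f"bin_width must be >= 1, got {bin_width}")
    bins: list[GenomicRegion] = []
    for chrom in sorted(genome):
        length = genome[chrom]
        for start in range(0, length, bin_width):
            bins.append(GenomicRegion(chrom, start, min(start + bin_width, length)))
    return bins


def simulate_interaction_data(
    genome: Mapping[str, int] | None = None,
    n: int = 1000,
    m_samples: int = 2,
    seed: int = 0,
    intra_fraction: float = 0.7,
    decay_exponent: float = 1.0,
    anchor_width: int = 1000,
) -> AssaySet:
    """Simulate an :class:`~pairspace.assay.AssaySet` of ``n`` interactions.

    Anchors are ``anchor_width``-wide windows placed uniformly on
    chromosomes drawn proportionally to length (clamped to the chromosome
    when it is shorter than the window).  Each interaction is cis with
    probability ``intra_fraction``.  One ``"counts"`` assay holds negative
    binomial counts (dispersion size 0.5) whose mean is
    ``10 * (1 + d_kb) ** -decay_exponent`` for cis pairs — ``d_kb`` the
    mid-to-mid anchor distance in kilobases, so the base mean of 10 applies
    to near-adjacent anchors and the decay stays visible at megabase
    scale — and a flat 1 for trans pairs.

    The same seed always yields an identical object.
    """
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    _validate_genome(genome)
    if n < 0 or m_samples < 0:
        raise ValidationError("n and m_samples must be non-negative")
    if not 0.0 <= intra_fraction <= 1.0:
        raise ValidationError(f"intra_fraction must be in [0, 1], got {intra_fraction}")
    if decay_exponent <= 0:
        raise ValidationError(f"decay_exponent must be positive, got {decay_exponent}")
    if len(genome) < 2 and intra_fraction < 1.0:
        raise ValidationError("trans interactions need at least two chromosomes")

    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def draw_anchor(chrom_idx: int) -> GenomicRegion:
        chrom = chroms[chrom_idx]
        width = min(anchor_width, genome[chrom])
        start = int(rng.integers(0, genome[chrom] - width + 1))
        return GenomicRegion(chrom, start, start + width)

    anchors1: list[GenomicRegion] = []
    anchors2: list[GenomicRegion] = []
    for _ in range(n):
        c1 = int(rng.choice(len(chroms), p=weights))
        if rng.random() < intra_fraction:
            c2 = c1
        else:
            others = [c for c in range(len(chroms)) if c != c1]
            w = weights[others] / weights[others].sum()
            c2 = int(rng.choice(others, p=w))
        anchors1.append(draw_anchor(c1))
        anchors2.append(draw_anchor(c2))

    table = make_interactions(anchors1, anchors2)

    mu = np.empty(n)
    for i, (a, b) in enumerate(zip(anchors1, anchors2)):
        if a.chrom == b.chrom:
            d_kb = abs(b.midpoint - a.midpoint) / 1000.0
            mu[i] = 10.0 * (1.0 + d_kb) ** (-decay_exponent)
        else:
            mu[i] = 1.0
    size = 0.5  # NB dispersion parameter (smaller = more overdispersed)
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p[:, None], size=(n, m_samples)).astype(np.int64)

    sample_metadata = pd.DataFrame({"sample": [f"sample{j + 1}" for j in range(m_samples)]})
    return make_assay_set(
        table,
        {"counts": counts},
        sample_metadata,
        {"seed": seed, "genome": genome},
    )
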