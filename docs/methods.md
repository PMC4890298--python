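# Methods

## The interaction data model

A pairwise interaction connects two genomic anchors. `pairspace` stores
anchors indirectly: a `RegionSet` holds each distinct region exactly once,
strictly sorted, and an `InteractionTable` holds two parallel vectors of
integer indices into it. This mirrors how mature interaction containers are
built: coordinates are deduplicated (a promoter engaged in hundreds of loops
is stored once), and per-region computations are done over the small
reference set and broadcast back through the indices.

Conventions, fixed once and used everywhere:

- **Coordinates** are 0-based half-open, the native BEDPE/BED convention, so
  file round trips are bit-exact. Any 1-based closed display would be
  presentation-only.
- **Canonical order** is chromosome name (lexicographic by default — so
  `chr10 < chr2`; an explicit chromosome-order list may be given at
  construction and then governs all sorting), then start, then end, then
  strand in the order `+`, `-`, `.`. The reference-set order is a package
  convention: nothing downstream depends on which total order is used, only
  on it being strict and deterministic.
- **Zero-width regions are rejected** at validation. Under half-open
  coordinates they contain no bases, which makes overlap semantics
  ambiguous.
- **Strand is stored but ignored** by every overlap and distance operation;
  it participates only in region identity and sorting. No method of this
  data model conditions on strand.
- **Strict mode** (`anchor1 <= anchor2` per row) is a flag on the one table
  type rather than a separate class; it is established at construction by
  swapping, validated as an invariant, and preserved by `concat` and row
  subsetting.
- **Duplicates** are defined on stored index pairs as-is. Symmetric
  duplicate detection is deliberately a two-step recipe —
  `swap_anchors` then `deduplicate` — keeping each step deterministic and
  composable.

## Overlap semantics

The primitive `region_overlap(a, b, maxgap, minoverlap)` is true iff the
regions share a chromosome and either the intersection length is at least
`minoverlap` (default 1), or `minoverlap == 1` and the gap between them is
at most `maxgap` (default 0). Abutting half-open intervals have gap 0 and
therefore overlap under the defaults. Setting `minoverlap > 1` disables the
gap rule. The defaults give plain intersection, matching common
interval-query semantics.

On top of this primitive:

- **1D** (`overlaps_any_region`): an interaction overlaps an interval if
  *either* anchor overlaps it. A hit is reported once per (interaction,
  subject) even when both anchors hit.
- **2D** (`overlaps_pair`): an interaction overlaps a pair of intervals if
  one anchor overlaps one interval and the other anchor the other, trying
  both assignments; the operation is symmetric in its two intervals.
- **Table vs table** (`overlaps_interactions`): anchors must overlap
  pairwise. "Corresponding anchors" is read permissively — either pairing
  (first-with-first or first-with-second) counts; `match_slots=True`
  restricts to same-slot matching for callers who want the stricter
  reading. Both behaviours are exposed rather than guessing a single one.
- **Linking** (`link_overlaps`): given one or two sets of regions of
  interest (e.g. genes and enhancers), report triplets (interaction,
  subject, subject) where the two anchors land in the two sets. In
  single-set mode triplets are canonicalized to `p <= q` and deduplicated;
  self-pairs (both anchors in the same region) are kept — callers filter
  them if unwanted.

Subject lookups run through per-chromosome interval trees with an exact
predicate post-filter (queries are padded by `maxgap + 1` so gap candidates
reach the tree). The trees are an engine detail; the test suite checks every
operation against an exhaustive all-pairs enumeration with a base-by-base
overlap oracle.

## Distances, bounding boxes, cis/trans

For a cis interaction with left anchor L (smaller start; ties broken by
end) and right anchor R:

- `mid` = |midpoint(R) − midpoint(L)| with half-open midpoints
  `(start + end) / 2`; half-integral values are reported as-is, not rounded.
- `gap` = `max(0, R.start − L.end)` — 0 for touching or overlapping anchors.
- `span` = `max(end) − min(start)`.

For disjoint cis anchors these satisfy `span = gap + width1 + width2`.
Trans interactions have no linear distance; all modes return NaN, the
idiomatic NumPy missing marker (the cis/trans flag is available separately
as `is_intra`). These distances feed distance-decay diagnostics; fitting the
decay trend itself is out of scope.

`bounding_box` summarizes a group of interactions by the smallest
axis-aligned rectangle containing them in interaction space. Rows are first
canonicalized with `swap_anchors` so slot membership is well defined; each
slot of a group must then live on a single chromosome (mixed chromosomes
raise an error naming the group), and the box per slot is
`[min start, max end]`. Minimality is testable: every member anchor lies in
its box and each box edge is attained by some member.

## Linearization (virtual 4C)

Given a bait region, `linearize` selects the interactions with a 1D overlap
with the bait, and for each reports the anchor that does *not* overlap the
bait, carrying that interaction's assay rows over unchanged. The output is a
per-region signal track on the linear genome, the shape of 4C data around a
viewpoint. Two deliberate choices:

- Interactions whose **both** anchors overlap the bait are dropped by
  default: the extraction rule is undefined for them, and reporting either
  anchor would fabricate a signal region. `keep_double=True` keeps them,
  reporting the canonical slot-1 anchor.
- Rows are **not aggregated**: several interactions may report the same
  region, and each keeps its own row — extraction is per-interaction.
  Smoothing or normalizing the linearized signal is out of scope.

Bait overlap uses the default predicate parameters (`maxgap=0`,
`minoverlap=1`).

## Contact matrices

`ContactMatrix` is the grid view of interaction space: row and column
regions (indices into a region set) and an r × c value grid. A cell may be
*empty*, which is distinct from a stored zero — an unmeasured bin is not a
zero-count bin. The dense backend keeps a float grid plus a boolean
filled-mask; the sparse backend (`scipy.sparse`) stores only non-empty
cells and represents empty as structural absence. Because a stored zero in
a sparse matrix would be indistinguishable from absence on conversion back,
stored zeros are rejected in the sparse backend; this keeps the two
backends logically equivalent, and the tests verify they deflate
identically.

`inflate` matches interactions to cells by **exact coordinate identity**
between anchors and row/column regions, in either anchor order (so one
interaction fills both (i, j) and (j, i) when both orderings exist in the
grid). Overlap-based assignment or binning is deliberately not done here —
that is the caller's job via `tile_genome` or external tools — because
identity matching is what makes `inflate`/`deflate` a lossless pair. When
several distinct interactions map to one cell the `combine` policy decides:
`error` (default), `sum`, or `first`. `deflate` emits one interaction per
non-empty cell, canonically sorted, with values as a metadata column;
`swap_anchors` + `deduplicate` reconcile the symmetric duplicates that
either-order matching creates. Matrices are not forced symmetric.

## File formats

BEDPE is parsed strictly: tab-separated, ≥ 6 columns, `#`/`track` lines
skipped, `.` as the missing marker, parse errors reported with the line
number. Columns 7–10 are name, score (parsed as a number when possible,
kept as text otherwise) and the two strands; columns beyond 10 are
preserved as opaque extra metadata and re-emitted on write, since loop
callers commonly append columns. `write_bedpe` then `read_bedpe` is exact,
and write–read–write is byte-stable; numeric formatting prints integers
without a decimal point and half-integral values with one decimal so text
outputs are reproducible byte-for-byte. BED3/BED4 is read for subject and
bait regions; linear tracks export as bedGraph (one file per sample per
assay); matrices serialize as COO triplet text (`chrom:start-end` labels)
or dense TSV with `NA` for empty cells.

The CLI (`pairspace dist|overlap|linearize|bbox|convert|simulate`) is a
thin shell over these functions: tab-separated text on stdout, logs on
stderr, exit 0 on success, 1 on data errors, 2 on usage errors. The test
suite checks each subcommand against the equivalent library call.

## Synthetic data

`simulate_interaction_data` drives everything from one
`numpy.random.Generator` seeded explicitly — no global randomness — so a
seed fully determines the output. It emulates the gross shape of Hi-C pair
data on a toy genome (default two chromosomes, 1 Mb and 0.8 Mb):

- anchors are fixed-width windows (default 1 kb) placed uniformly, on
  chromosomes drawn proportionally to length;
- each interaction is cis with probability `intra_fraction` (default 0.7,
  a typical cis-majority mix);
- one `"counts"` assay holds negative binomial counts with dispersion
  (size) 0.5. The cis mean is `10 · (1 + d_kb)^(−decay_exponent)` where
  `d_kb` is the mid-to-mid anchor distance in **kilobases** — so the base
  mean of 10 applies to near-adjacent anchors and the decay remains visible
  at megabase scale rather than collapsing all counts to zero — and the
  trans mean is a flat 1.

Only sign and ordering properties of the counts are asserted (e.g. the
negative rank correlation between cis distance and mean count), never exact
stochastic values. The generator does **not** emulate TADs, compartments,
restriction-fragment structure or library-size effects; passing tests
demonstrate the correctness of the data model and its operations, not
biological realism of the fixtures.

## Verification sizes and numerical notes

The brute-force oracles enumerate bases and pairs, so fixtures are kept
small: coordinates up to a few kb, tables up to 200 interactions, 50
subjects, 20 seeded fixtures per suite; distances are checked on 1000
random pairs and boxes on 100 random groups; BEDPE round trips use
1000-row tables. These sizes exercise every code path while keeping the
whole suite fast. All comparisons are exact (integer coordinates, exact
float arithmetic on sums of integers and halves); no tolerances are needed
anywhere.

Known limitations: no binned/overlap-based matrix construction, no matrix
balancing or normalization, no distance-trend fitting, no strand-aware
overlaps, no binary Hi-C container formats (.hic, .cool), and no
interaction-level statistics — this package is the layer such tools build
on.
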