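# pairspace

Containers and methods for **pairwise genomic-interaction data** from Hi-C,
ChIA-PET and related chromosome-conformation experiments.

Hi-C-style experiments report pairs of interacting genomic loci ("anchors")
together with per-sample measurements such as read-pair counts. Analysing
them needs infrastructure that downstream tools can share: a memory-efficient
interaction table, a container binding interactions to experimental data
matrices, a contact-matrix view of the two-dimensional interaction space, and
the low-level geometric operations — 1D/2D overlaps, region linking, anchor
distances, bounding boxes, virtual-4C linearization — that higher-level
statistics are built on. `pairspace` provides exactly that layer for Python,
with plain-text interchange (BEDPE, BED, bedGraph, COO/dense TSV) and a small
CLI.

## Data model

All coordinates are 0-based half-open (BEDPE-native).

- **`GenomicRegion`** — one interval `(chrom, start, end, strand)`.
- **`RegionSet`** — the single coordinate store: a strictly sorted,
  deduplicated list of regions. Every anchor is an integer index into it, so
  a region used by many interactions is stored once.
- **`InteractionTable`** — parallel anchor-index vectors `anchor1`,
  `anchor2` plus per-interaction metadata columns. In *strict* mode each row
  is canonicalized so `anchor1 <= anchor2`.
- **`AssaySet`** — an `InteractionTable` (n rows) with named `n x m` assay
  matrices (one column per sample) and sample metadata.
- **`ContactMatrix`** — the interaction space as a grid: row/column region
  indices plus a dense or sparse value grid, where an *empty* cell is
  distinct from a stored zero.

Key operations: `region_overlap` (intersection with `maxgap`/`minoverlap`
semantics), `overlaps_any_region` (1D: either anchor hits the interval),
`overlaps_pair` and `overlaps_interactions` (2D: both anchors hit, either
assignment), `link_overlaps` (interactions linking genes to enhancers),
`pair_distance` (`mid`/`gap`/`span`, NaN for trans pairs), `bounding_box`
(minimum per-group box in interaction space), `linearize` (4C-like
projection around a bait), `inflate`/`deflate` (lossless table ↔ matrix
conversion by exact coordinate identity), and BEDPE/BED/COO I/O.

## Worked example

```python
import numpy as np
from pairspace import *

t = make_interactions(
    [GenomicRegion("chr1", 100, 200), GenomicRegion("chr1", 300, 400), GenomicRegion("chr2", 0, 50)],
    [GenomicRegion("chr2", 50, 100), GenomicRegion("chr1", 5000, 6000), GenomicRegion("chr2", 500, 600)],
)
print("cis flags:", is_intra(t).tolist())
print("gap distances:", pair_distance(t, "gap").tolist())

aset = make_assay_set(t, {"counts": np.array([[5, 2], [1, 0], [7, 7]])})
track = linearize(aset, GenomicRegion("chr1", 0, 1000))
for r, row in zip(track.regions, track.assays["counts"]):
    print(f"{r}\tcounts={row.tolist()}")
```

prints

```
cis flags: [False, True, True]
gap distances: [nan, 4600.0, 450.0]
chr2:50-100	counts=[5, 2]
chr1:5000-6000	counts=[1, 0]
```

The first interaction is trans (chr1–chr2), so its linear distance is
undefined (`nan`); the other two are cis with 4600 bp and 450 bp between
their anchors. Linearizing against the bait `chr1:0-1000` keeps the two
interactions with exactly one anchor in the bait and reports the *other*
anchor with its counts carried over — a virtual-4C track around the bait.
The third interaction never touches the bait and is dropped.

The same operations are available from the shell:

```sh
pairspace simulate --n 100 --seed 7 > loops.bedpe
pairspace dist --bedpe loops.bedpe --mode gap
pairspace linearize --bedpe loops.bedpe --bait chr1:0-200000
```

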