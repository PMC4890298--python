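"""Readers and writers for the plain-text interchange formats.

Supported formats, all tab-separated and 0-based half-open:

- **BEDPE** (6-10+ columns): pairwise interactions.  Columns 7-10 are
  name, score, strand1, strand2; ``.`` marks a missing value.  Columns
  beyond 10 are preserved verbatim as opaque extra metadata (common in
  loop-caller output).  ``read_bedpe`` and ``write_bedpe`` round-trip
  byte-identically on files produced by ``write_bedpe``.
- **BED3/BED4**: plain regions, optional name labels.
- **bedGraph**: per-sample export of a linearized 4C-like track.
- **COO triplet text** and **dense TSV**: contact-matrix serialization,
  with regions labelled ``chrom:start-end``.
"""

from __future__ import annotations

import re
from typing import IO, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .assay import LinearTrack
from .interactions import InteractionTable, make_interactions
from .matrix import ContactMatrix
from .regions import GenomicRegion, ValidationError, build_region_set

__all__ = [
    "ParseError",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "write_bedgraph",
    "write_coo",
    "read_coo",
    "write_dense",
    "parse_region_label",
    "format_number",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _data_lines(source: IO[str]):
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        yield lineno, line


def _parse_coord(text: str, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(lineno, f"non-integer {what} {text!r}") from None


def _parse_region(chrom: str, start: str, end: str, lineno: int, strand: str = ".") -> GenomicRegion:
    s = _parse_coord(start, lineno, "start")
    e = _parse_coord(end, lineno, "end")
    try:
        return GenomicRegion(chrom, s, e, strand)
    except ValidationError as err:
        raise ParseError(lineno, str(err)) from None


def _parse_score(text: str):
    if text == ".":
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def format_number(value) -> str:
    """Integer-valued numbers without a decimal point, others as repr.

    Half-integral midpoints print with one decimal (e.g. ``150.5``); this
    keeps text outputs byte-stable across runs.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "."
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        f = float(value)
        if f.is_integer():
            return str(int(f))
        return repr(f)
    return str(value)


def read_bedpe(source: IO[str], strict: bool = False) -> InteractionTable:
    """Parse BEDPE into an :class:`InteractionTable`.

    One interaction per record; ``name``, ``score``, ``strand1``/``strand2``
    and any extra columns become metadata columns.  ``#`` and ``track``
    lines are skipped; missing fields (``.``) become None.  Coordinates are
    taken verbatim (0-based half-open).
    """
    anchors1: list[GenomicRegion] = []
    anchors2: list[GenomicRegion] = []
    names: list = []
    scores: list = []
    strands1: list[str] = []
    strands2: list[str] = []
    extras: list[list[str]] = []
    n_extra = 0
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(lineno, f"expected >= 6 tab-separated columns, got {len(fields)}")
        s1 = fields[8] if len(fields) > 8 else "."
        s2 = fields[9] if len(fields) > 9 else "."
        for s in (s1, s2):
            if s not in _STRANDS:
                raise ParseError(lineno, f"invalid strand {s!r}")
        anchors1.append(_parse_region(fields[0], fields[1], fields[2], lineno, s1))
        anchors2.append(_parse_region(fields[3], fields[4], fields[5], lineno, s2))
        names.append(None if len(fields) < 7 or fields[6] == "." else fields[6])
        scores.append(_parse_score(fields[7]) if len(fields) > 7 else None)
        strands1.append(s1)
        strands2.append(s2)
        extra = fields[10:]
        extras.append(extra)
        n_extra = max(n_extra, len(extra))
    metadata = pd.DataFrame(
        {
            "name": pd.Series(names, dtype=object),
            "score": pd.Series(scores, dtype=object),
            "strand1": pd.Series(strands1, dtype=object),
            "strand2": pd.Series(strands2, dtype=object),
        }
    )
    for k in range(n_extra):
        metadata[f"extra{k + 1}"] = pd.Series(
            [row[k] if k < len(row) else None for row in extras], dtype=object
        )
    return make_interactions(anchors1, anchors2, metadata=metadata, strict=strict)


def write_bedpe(table: InteractionTable, sink: IO[str]) -> int:
    """Write a table as 10+-column BEDPE; returns the record count.

    ``name``/``score``/``strand1``/``strand2`` metadata columns are emitted
    when present (``.`` for missing values) and ``extra*`` columns follow in
    order.  Strand columns default to each anchor's stored strand.
    """
    def _field(v) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "."
        return str(v)

    md = table.metadata
    first = table.first_anchors()
    second = table.second_anchors()
    extra_cols = sorted(
        (c for c in md.columns if re.fullmatch(r"extra\d+", str(c))),
        key=lambda c: int(str(c)[5:]),
    )
    n = 0
    for i in range(len(table)):
        a, b = first[i], second[i]
        name = md["name"].iloc[i] if "name" in md else None
        score = md["score"].iloc[i] if "score" in md else None
        s1 = md["strand1"].iloc[i] if "strand1" in md else a.strand
        s2 = md["strand2"].iloc[i] if "strand2" in md else b.strand
        fields = [
            a.chrom, str(a.start), str(a.end),
            b.chrom, str(b.start), str(b.end),
            _field(name),
            format_number(score),
            _field(s1),
            _field(s2),
        ]
        for c in extra_cols:
            fields.append(_field(md[c].iloc[i]))
        sink.write("\t".join(fields) + "\n")
        n += 1
    return n


def read_bed(source: IO[str]) -> tuple[list[GenomicRegion], list]:
    """Parse BED3/BED4+ into regions plus parallel name labels (None if absent)."""
    regions: list[GenomicRegion] = []
    names: list = []
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(lineno, f"expected >= 3 tab-separated columns, got {len(fields)}")
        regions.append(_parse_region(fields[0], fields[1], fields[2], lineno))
        names.append(fields[3] if len(fields) > 3 and fields[3] != "." else None)
    return regions, names


def write_bedgraph(track: LinearTrack, assay: str, sample: int, sink: IO[str]) -> int:
    """Write one sample column of one assay of a linear track as bedGraph."""
    if assay not in track.assays:
        raise KeyError(f"no assay named {assay!r}; have {sorted(track.assays)}")
    mat = track.assays[assay]
    if not 0 <= sample < mat.shape[1]:
        raise IndexError(f"sample index {sample} out of range for {mat.shape[1]} samples")
    n = 0
    for region, value in zip(track.regions, mat[:, sample]):
        sink.write(f"{region.chrom}\t{region.start}\t{region.end}\t{format_number(value)}\n")
        n += 1
    return n


def parse_region_label(label: str, lineno: int = 0) -> GenomicRegion:
    """Parse a ``chrom:start-end`` label back into a region."""
    m = re.fullmatch(r"(.+):(\d+)-(\d+)", label)
    if not m:
        raise ParseError(lineno, f"malformed region label {label!r}; expected chrom:start-end")
    return _parse_region(m.group(1), m.group(2), m.group(3), lineno)


def write_coo(cm: ContactMatrix, sink: IO[str]) -> int:
    """Write non-empty cells as ``row_region  col_region  value`` triplets."""
    mask = cm.filled_mask()
    grid = cm.dense_values()
    rows = cm.row_regions()
    cols = cm.col_regions()
    n = 0
    for i, j in zip(*np.nonzero(mask)):
        sink.write(f"{rows[i]}\t{cols[j]}\t{format_number(grid[i, j])}\n")
        n += 1
    return n


def read_coo(source: IO[str], backend: str = "sparse") -> ContactMatrix:
    """Read COO triplet text back into a :class:`ContactMatrix`.

    Row/column region lists are the distinct labels in order of first
    appearance on each axis.
    """
    row_regions: list[GenomicRegion] = []
    col_regions: list[GenomicRegion] = []
    row_pos: dict[GenomicRegion, int] = {}
    col_pos: dict[GenomicRegion, int] = {}
    entries: list[tuple[int, int, float]] = []
    for lineno, line in _data_lines(source):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(lineno, f"expected 3 columns (row, col, value), got {len(fields)}")
        r = parse_region_label(fields[0], lineno)
        c = parse_region_label(fields[1], lineno)
        try:
            v = float(fields[2])
        except ValueError:
            raise ParseError(lineno, f"non-numeric value {fields[2]!r}") from None
        if r not in row_pos:
            row_pos[r] = len(row_regions)
            row_regions.append(r)
        if c not in col_pos:
            col_pos[c] = len(col_regions)
            col_regions.append(c)
        entries.append((row_pos[r], col_pos[c], v))
    rset, index_map = build_region_set(row_regions + col_regions)
    rows = np.asarray(index_map[: len(row_regions)], dtype=np.int64)
    cols = np.asarray(index_map[len(row_regions):], dtype=np.int64)
    shape = (len(rows), len(cols))
    ii = np.array([e[0] for e in entries], dtype=np.int64)
    jj = np.array([e[1] for e in entries], dtype=np.int64)
    vv = np.array([e[2] for e in entries], dtype=float)
    if backend == "sparse":
        return ContactMatrix(
            rset, rows, cols, sp.coo_matrix((vv, (ii, jj)), shape=shape), None, "sparse"
        )
    grid = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    grid[ii, jj] = vv
    mask[ii, jj] = True
    return ContactMatrix(rset, rows, cols, grid, mask, "dense")


def write_dense(cm: ContactMatrix, sink: IO[str], empty: str = "NA") -> None:
    """Write the full grid as TSV with region labels in the header and margin."""
    grid = cm.dense_values()
    mask = cm.filled_mask()
    cols = cm.col_regions()
    rows = cm.row_regions()
    sink.write("region\t" + "\t".join(str(c) for c in cols) + "\n")
    for i, r in enumerate(rows):
        cells = [
            format_number(grid[i, j]) if mask[i, j] else empty
            for j in range(len(cols))
        ]
        sink.write(str(r) + "\t" + "\t".join(cells) + "\n")
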