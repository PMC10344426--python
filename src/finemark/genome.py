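"""Genomic coordinate conventions, interval containers, and flat-file I/O.

All coordinates are 0-based half-open throughout the package; GFF3 input
(1-based inclusive) is converted on read.  Interval collections are plain
pandas DataFrames with columns ``chrom``, ``start``, ``end`` and optionally
``name``, ``score``, ``strand`` — the natural interchange with BED.

Overlap primitives use the sorted-array counting identity: the number of
intervals in B overlapping query [s, e) by >= 1 bp equals
``#{b.start < e} - #{b.end <= s}`` (the two excluded sets are disjoint
whenever s < e).  Strand is ignored by all overlap computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]
BED_OPTIONAL_COLUMNS = ["name", "score", "strand"]


class BedFormatError(ValueError):
    """A BED/GFF3 line could not be parsed; message names the line number."""


class IntervalError(ValueError):
    """An interval violates the coordinate invariants (start < end, in-bounds)."""


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths defining the coordinate space.

    Parameters
    ----------
    lengths
        Mapping of chromosome name to length in bp.  Names must be unique
        (guaranteed by the mapping) and lengths strictly positive.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise IntervalError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return int(self.lengths[chrom])

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``chrom\\tlength`` chromosome-sizes file."""
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise BedFormatError(f"{path}: line {i}: expected 'chrom\\tlength'")
            name, raw = parts
            if name in lengths:
                raise BedFormatError(f"{path}: line {i}: duplicate chromosome {name!r}")
            lengths[name] = int(raw)
        return cls(lengths)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{int(length)}\n")


# ---------------------------------------------------------------------------
# interval frames
# ---------------------------------------------------------------------------


def make_intervals(
    chrom: Iterable[str],
    start: Iterable[int],
    end: Iterable[int],
    **optional: Iterable,
) -> pd.DataFrame:
    """Assemble and validate an interval frame from column vectors."""
    df = pd.DataFrame({"chrom": list(chrom), "start": list(start), "end": list(end)})
    for key, values in optional.items():
        if key not in BED_OPTIONAL_COLUMNS:
            raise ValueError(f"unknown interval column {key!r}")
        df[key] = list(values)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    validate_intervals(df)
    return df


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout | None = None) -> None:
    """Raise :class:`IntervalError` unless every interval satisfies
    0 <= start < end (<= chrom length, when a layout is supplied)."""
    if len(df) == 0:
        return
    if (df["start"].to_numpy() < 0).any():
        raise IntervalError("negative start coordinate")
    bad = df["start"].to_numpy() >= df["end"].to_numpy()
    if bad.any():
        row = df[bad].iloc[0]
        raise IntervalError(
            f"empty or inverted interval {row['chrom']}:{row['start']}-{row['end']}"
        )
    if layout is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in layout:
                raise IntervalError(f"unknown chromosome {chrom!r}")
            if (sub["end"].to_numpy() > layout[chrom]).any():
                raise IntervalError(f"interval beyond end of {chrom} (length {layout[chrom]})")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def empty_intervals(extra: Iterable[str] = ()) -> pd.DataFrame:
    cols = INTERVAL_COLUMNS + list(extra)
    df = pd.DataFrame({c: [] for c in cols})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# BED read/write
# ---------------------------------------------------------------------------

_SKIP = re.compile(r"^(#|track\b|browser\b)")


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a 3–6 column BED file into an interval frame, preserving order.

    Raises :class:`BedFormatError` naming the offending line on malformed
    input and :class:`IntervalError` on empty/inverted intervals or, when a
    *layout* is supplied, intervals outside it.
    """
    rows: list[tuple] = []
    ncols = 0
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or _SKIP.match(line):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or len(parts) > 6:
            raise BedFormatError(f"{path}: line {i}: expected 3-6 tab-separated columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BedFormatError(f"{path}: line {i}: non-integer coordinate") from exc
        if start >= end:
            raise IntervalError(f"{path}: line {i}: start {start} >= end {end}")
        name = parts[3] if len(parts) > 3 else None
        score: float | None = None
        if len(parts) > 4 and parts[4] != ".":
            try:
                score = float(parts[4])
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {i}: non-numeric score") from exc
        strand = parts[5] if len(parts) > 5 else None
        if strand is not None and strand not in {"+", "-", "."}:
            raise BedFormatError(f"{path}: line {i}: bad strand {strand!r}")
        rows.append((parts[0], start, end, name, score, strand))
        ncols = max(ncols, len(parts))
    columns = (INTERVAL_COLUMNS + BED_OPTIONAL_COLUMNS)[: max(ncols, 3)]
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS + BED_OPTIONAL_COLUMNS)[columns]
    if len(df) == 0:
        df = empty_intervals(columns[3:])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    validate_intervals(df, layout)
    return df


def _format_score(score) -> str:
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "."
    f = float(score)
    return str(int(f)) if f == int(f) else repr(f)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write an interval frame as BED (as many of the 6 columns as present).

    Round-trips with :func:`read_bed`: coordinates and scores are bit-exact.
    """
    validate_intervals(df)
    present = [c for c in BED_OPTIONAL_COLUMNS if c in df.columns]
    # BED columns are positional: emit up to the last present optional column.
    if present:
        upto = BED_OPTIONAL_COLUMNS.index(present[-1]) + 1
    else:
        upto = 0
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end))]
            if upto >= 1:
                name = getattr(row, "name", None) if "name" in df.columns else None
                fields.append("." if name is None else str(name))
            if upto >= 2:
                fields.append(_format_score(getattr(row, "score", None) if "score" in df.columns else None))
            if upto >= 3:
                strand = getattr(row, "strand", None) if "strand" in df.columns else None
                fields.append("." if strand is None else str(strand))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene models: one stranded body interval per gene plus optional exons.

    ``genes`` has columns gene_id, chrom, start, end, strand, tss;
    the TSS is body start on '+' and body end − 1 on '−'.
    ``exons`` (possibly empty) has columns gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame = field(default_factory=lambda: empty_intervals(["name"]).rename(columns={"name": "gene_id"}))

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise BedFormatError(f"duplicate gene_id {dup!r}")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise BedFormatError(
                f"gene {self.genes.loc[bad, 'gene_id'].iloc[0]!r} lacks a +/- strand"
            )
        validate_intervals(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _tss_from_strand(start: np.ndarray, end: np.ndarray, strand: np.ndarray) -> np.ndarray:
    return np.where(strand == "+", start, end - 1).astype(np.int64)


_GFF_ATTR = re.compile(r"(?:^|;)\s*(ID|gene_id|Parent)=([^;]+)")


def read_gene_annotation(path: str | Path, format: str = "gff3") -> GeneAnnotation:
    """Read gene models from GFF3 (``gene``/``exon`` records) or BED6.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Genes without a +/− strand or with duplicate ids are rejected.
    """
    if format not in {"gff3", "bed"}:
        raise ValueError(f"unknown annotation format {format!r}")
    if format == "bed":
        df = read_bed(path)
        if "strand" not in df.columns or "name" not in df.columns:
            raise BedFormatError(f"{path}: BED gene annotation requires 6 columns")
        genes = df.rename(columns={"name": "gene_id"})[["gene_id", "chrom", "start", "end", "strand"]].copy()
        genes["tss"] = _tss_from_strand(
            genes["start"].to_numpy(), genes["end"].to_numpy(), genes["strand"].to_numpy()
        )
        return GeneAnnotation(genes.reset_index(drop=True))

    gene_rows, exon_rows = [], []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise BedFormatError(f"{path}: line {i}: expected 9 GFF3 columns")
        chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = parts
        if ftype not in {"gene", "exon"}:
            continue
        try:
            start, end = int(start1) - 1, int(end1)
        except ValueError as exc:
            raise BedFormatError(f"{path}: line {i}: non-integer coordinate") from exc
        fields = dict(_GFF_ATTR.findall(attrs))
        if ftype == "gene":
            if strand not in {"+", "-"}:
                raise BedFormatError(f"{path}: line {i}: gene record lacks strand")
            gid = fields.get("ID") or fields.get("gene_id")
            if gid is None:
                raise BedFormatError(f"{path}: line {i}: gene record lacks ID")
            gene_rows.append((gid, chrom, start, end, strand))
        else:
            parent = fields.get("Parent") or fields.get("gene_id")
            if parent is not None:
                exon_rows.append((parent, chrom, start, end))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes["start"] = genes["start"].astype(np.int64)
    genes["end"] = genes["end"].astype(np.int64)
    genes["tss"] = _tss_from_strand(
        genes["start"].to_numpy(), genes["end"].to_numpy(), genes["strand"].to_numpy()
    )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    exons["start"] = exons["start"].astype(np.int64)
    exons["end"] = exons["end"].astype(np.int64)
    return GeneAnnotation(genes, exons)


# ---------------------------------------------------------------------------
# fragment sets
# ---------------------------------------------------------------------------


@dataclass
class FragmentSet:
    """One sample's sequenced fragments as unstranded genomic intervals."""

    sample_id: str
    condition: str
    replicate: int
    target: str
    fragments: pd.DataFrame  # chrom, start, end

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        validate_intervals(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    def with_fragments(self, fragments: pd.DataFrame) -> "FragmentSet":
        return FragmentSet(self.sample_id, self.condition, self.replicate, self.target, fragments)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Union of intervals, merging any two whose gap is <= *max_gap* bp.

    Follows ``bedtools merge -d`` semantics: bookended intervals merge at
    max_gap 0.  Output is sorted and non-overlapping.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if len(df) == 0:
        return empty_intervals()
    out_chrom, out_start, out_end = [], [], []
    for chrom, sub in sort_intervals(df[INTERVAL_COLUMNS]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        # new run begins where the gap to everything before exceeds max_gap
        breaks = np.flatnonzero(starts[1:] > ends[:-1] + max_gap) + 1
        run_start = np.concatenate(([0], breaks))
        run_end = np.concatenate((breaks, [len(sub)]))
        out_chrom.extend([chrom] * len(run_start))
        out_start.extend(starts[run_start].tolist())
        out_end.extend(ends[run_end - 1].tolist())
    return make_intervals(out_chrom, out_start, out_end)


def _by_chrom_sorted(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chrom -> (sorted starts, sorted ends); the two arrays are sorted
    independently, which is all the counting identity needs."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = (np.sort(sub["start"].to_numpy()), np.sort(sub["end"].to_numpy()))
    return out

def count_overlaps(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """For each query interval, the number of subject intervals overlapping
    it by >= 1 bp.  A subject overlapping two queries is counted in both."""
    index = _by_chrom_sorted(subjects)
    queries = queries.reset_index(drop=True)
    counts = np.zeros(len(queries), dtype=np.int64)
    for chrom, sub in queries.groupby("chrom", sort=False):
        if chrom in index:
            starts, ends = index[chrom]
            n_start_before = np.searchsorted(starts, sub["end"].to_numpy(), side="left")
            n_end_before = np.searchsorted(ends, sub["start"].to_numpy(), side="right")
            counts[sub.index.to_numpy()] = n_start_before - n_end_before
    return counts


def overlaps_any(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean flag per query: does it overlap any subject by >= 1 bp?"""
    return count_overlaps(queries, subjects) > 0


def total_bp(df: pd.DataFrame) -> int:
    """Total bp covered, counting overlapping input intervals once."""
    return int((lambda m: (m["end"] - m["start"]).sum())(merge_intervals(df)))
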