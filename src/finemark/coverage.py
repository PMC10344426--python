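"""Binned coverage tracks and between-sample normalization.

Three normalization schemes are provided:

* RPKM per bin — reads per kilobase per million mapped fragments,
  ``value * 1e9 / (bin_width * total_fragments)``;
* genome-wide z-score tracks — subtract the genome-wide mean bin value and
  divide by the population standard deviation over all bins of all
  chromosomes;
* TMM on reads-in-peaks — trimmed-mean-of-M-values factors computed from a
  regions x samples count matrix, combined into the final track scale
  ``1e6 / (tmm_factor * reads_in_peaks)``.  This normalizes histone-mark
  samples for depth *and* library composition without a spike-in.

The TMM estimator follows the published definition: reference column by
upper-quartile proximity to the mean, M/A log-ratios over regions nonzero
in both samples, double-tailed trims of 30% on M and 5% on A by ranks,
inverse delta-method variance weights, and a geometric-mean-1 rescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome import FragmentSet, GenomeLayout, count_overlaps, validate_intervals

TRACK_STATES = ("raw", "rpkm", "scaled", "zscore")
_ALLOWED_TRANSITIONS = {("raw", "rpkm"), ("raw", "scaled"), ("raw", "zscore"),
                        ("rpkm", "zscore"), ("scaled", "zscore")}


@dataclass
class BinnedTrack:
    """Fixed-bin-size per-chromosome value arrays with a normalization tag."""

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in TRACK_STATES:
            raise ValueError(f"unknown track state {self.state!r}")
        for chrom in self.layout.chroms:
            expect = -(-self.layout[chrom] // self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(expect)
            elif len(self.values[chrom]) != expect:
                raise ValueError(f"{chrom}: expected {expect} bins, got {len(self.values[chrom])}")
        if self.state == "raw" and any((v < 0).any() for v in self.values.values()):
            raise ValueError("raw track values must be non-negative")

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def bin_widths(self, chrom: str) -> np.ndarray:
        """True bp width of every bin; the terminal bin may be short."""
        n = self.n_bins(chrom)
        widths = np.full(n, self.bin_size, dtype=np.int64)
        widths[-1] = self.layout[chrom] - (n - 1) * self.bin_size
        return widths

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.layout.chroms])

    def _check_transition(self, new_state: str) -> None:
        if (self.state, new_state) not in _ALLOWED_TRANSITIONS:
            raise ValueError(f"illegal state transition {self.state} -> {new_state}")


def compute_coverage(
    fragments: FragmentSet | pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int,
    max_fragment_length: int | None = None,
    dedup: bool = False,
) -> BinnedTrack:
    """Raw binned coverage: each fragment adds 1 to every bin it overlaps
    by >= 1 bp.

    Fragments longer than *max_fragment_length* are excluded; with *dedup*,
    exact duplicates (same chrom/start/end) count once.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    frags = fragments.fragments if isinstance(fragments, FragmentSet) else fragments
    if max_fragment_length is not None:
        keep = (frags["end"] - frags["start"]) <= max_fragment_length
        frags = frags[keep]
    if dedup:
        frags = frags.drop_duplicates(subset=["chrom", "start", "end"])
    values: dict[str, np.ndarray] = {}
    for chrom in layout.chroms:
        n = -(-layout[chrom] // bin_size)
        diff = np.zeros(n + 1)
        sub = frags[frags["chrom"] == chrom]
        if len(sub):
            lo = sub["start"].to_numpy() // bin_size
            hi = (sub["end"].to_numpy() - 1) // bin_size  # last overlapped bin
            np.add.at(diff, lo, 1.0)
            np.add.at(diff, hi + 1, -1.0)
        values[chrom] = np.cumsum(diff[:-1])
    return BinnedTrack(layout, bin_size, values, "raw")


def to_rpkm(track: BinnedTrack, total_fragments: int) -> BinnedTrack:
    """RPKM-normalize a raw track; terminal short bins use their true width."""
    track._check_transition("rpkm")
    if track.state != "raw":
        raise ValueError("RPKM requires a raw track")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be > 0")
    values = {
        chrom: track.values[chrom] * 1e9 / (track.bin_widths(chrom) * total_fragments)
        for chrom in track.layout.chroms
    }
    return BinnedTrack(track.layout, track.bin_size, values, "rpkm")


def apply_scale(track: BinnedTrack, scale: float) -> BinnedTrack:
    """Multiply a raw track by a final scale factor (state raw -> scaled)."""
    track._check_transition("scaled")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    values = {c: track.values[c] * scale for c in track.layout.chroms}
    return BinnedTrack(track.layout, track.bin_size, values, "scaled")


def merge_replicates(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Per-bin arithmetic mean of replicate tracks on identical grids."""
    if not tracks:
        raise ValueError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or t.state != first.state or t.layout.lengths != first.layout.lengths:
            raise ValueError("tracks must share layout, bin size and state")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.layout.chroms
    }
    return BinnedTrack(first.layout, first.bin_size, values, first.state)


def zscore_normalize(track: BinnedTrack) -> BinnedTrack:
    """Genome-wide z-score: (v - mean) / population sd over all bins of all
    chromosomes.  A constant track (sd = 0) becomes all-zero with a warning."""
    track._check_transition("zscore")
    flat = track.all_values()
    mean = flat.mean()
    sd = flat.std()  # population sd
    if sd == 0:
        warnings.warn("track has zero variance; z-score output is all-zero")
        values = {c: np.zeros_like(track.values[c]) for c in track.layout.chroms}
    else:
        values = {c: (track.values[c] - mean) / sd for c in track.layout.chroms}
    return BinnedTrack(track.layout, track.bin_size, values, "zscore")


def count_in_regions(
    fragments: FragmentSet | pd.DataFrame, regions: pd.DataFrame
) -> np.ndarray:
    """Fragments overlapping each region by >= 1 bp (a fragment spanning two
    regions is counted in both)."""
    frags = fragments.fragments if isinstance(fragments, FragmentSet) else fragments
    validate_intervals(regions)
    return count_overlaps(regions, frags)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _quantile_type7(x: np.ndarray, p: float) -> float:
    return float(np.quantile(x, p))  # numpy 'linear' == R type 7


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    weighted: bool,
) -> float:
    both = (obs > 0) & (ref > 0)
    y, r = obs[both], ref[both]
    if both.sum() < 2:
        warnings.warn("fewer than 2 usable regions for TMM; factor set to 1")
        return 1.0
    p_obs, p_ref = y / lib_obs, r / lib_ref
    logR = np.log2(p_obs / p_ref)
    absE = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    v = (lib_obs - y) / (lib_obs * y) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = len(logR)
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rL = rankdata(logR)
    rS = rankdata(absE)
    keep = (rL >= loL) & (rL <= hiL) & (rS >= loS) & (rS <= hiS)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 regions retained after TMM trimming; factor set to 1")
        return 1.0
    if weighted:
        f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(logR[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    count_matrix: pd.DataFrame | np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """TMM normalization factors for a regions x samples count matrix.

    The reference sample is the one whose library-size-scaled upper
    quartile is closest to the mean upper quartile (ties to the lowest
    index).  Factors are rescaled to geometric mean 1, so a pure depth
    difference yields factors of exactly 1.
    """
    X = np.asarray(count_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("count matrix must be regions x samples with >= 2 samples")
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive column sum")
    f75 = np.array([_quantile_type7(X[:, k], 0.75) / lib[k] for k in range(X.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if k == ref
            else _tmm_pair(X[:, k], X[:, ref], lib[k], lib[ref], logratio_trim, sum_trim, weighted)
            for k in range(X.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


@dataclass(frozen=True)
class NormalizationResult:
    """One sample's reads-in-peaks normalization summary."""

    sample_id: str
    tmm_factor: float
    reads_in_peaks: int

    def __post_init__(self) -> None:
        if self.reads_in_peaks <= 0:
            raise ValueError("reads_in_peaks must be > 0")
        if self.tmm_factor <= 0:
            raise ValueError("tmm_factor must be > 0")

    @property
    def final_scale(self) -> float:
        return final_scale_factor(self.tmm_factor, self.reads_in_peaks)


def final_scale_factor(tmm_factor: float, reads_in_peaks: int) -> float:
    """Final track scale: ``1,000,000 / (tmm_factor * reads_in_peaks)``."""
    if tmm_factor <= 0 or reads_in_peaks <= 0:
        raise ValueError("tmm_factor and reads_in_peaks must be > 0")
    return 1_000_000.0 / (tmm_factor * reads_in_peaks)


def normalize_samples(
    count_matrix: pd.DataFrame, sample_ids: Sequence[str] | None = None
) -> list[NormalizationResult]:
    """TMM factors + reads-in-peaks + final scales for a count matrix whose
    columns are samples."""
    ids = list(sample_ids) if sample_ids is not None else list(count_matrix.columns)
    factors = tmm_factors(count_matrix)
    rips = np.asarray(count_matrix, dtype=float).sum(axis=0)
    return [
        NormalizationResult(sid, float(f), int(rip))
        for sid, f, rip in zip(ids, factors, rips)
    ]


# ---------------------------------------------------------------------------
# bedGraph serialization
# ---------------------------------------------------------------------------


def write_bedgraph(track: BinnedTrack, path: str | Path, dense: bool = False) -> None:
    """One line per (non-zero, unless *dense*) bin: chrom, start, end, value."""
    with open(path, "w") as fh:
        for chrom in track.layout.chroms:
            vals = track.values[chrom]
            widths = track.bin_widths(chrom)
            starts = np.arange(len(vals), dtype=np.int64) * track.bin_size
            ends = starts + widths
            for s, e, v in zip(starts, ends, vals):
                if dense or v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(
    path: str | Path, layout: GenomeLayout, bin_size: int, state: str = "raw"
) -> BinnedTrack:
    """Read a bin-aligned bedGraph back into a track (inverse of
    :func:`write_bedgraph`)."""
    values = {c: np.zeros(-(-layout[c] // bin_size)) for c in layout.chroms}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        chrom, s, _e, v = line.split("\t")
        idx = int(s) // bin_size
        if int(s) % bin_size:
            raise ValueError(f"{path}: line {i}: bin not aligned to grid")
        values[chrom][idx] = float(v)
    return BinnedTrack(layout, bin_size, values, state)
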