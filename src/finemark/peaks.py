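"""Narrow-peak calling and the peak post-processing chain.

The caller here is a deliberately simple, fully documented local-Poisson
scanner, not a MACS2 re-implementation: fixed windows are tested against
the most conservative of a genome-wide and two local (1 kb / 10 kb)
expected counts, BH-corrected, and significant adjacent windows joined.
Any deterministic caller with controlled false discovery suffices for the
downstream quantification, whose inputs are peak interval sets.

Post-processing mirrors standard practice for transcription-factor
CUT&RUN: keep sub-120-bp fragments (strictly < 120), keep high-confidence
peaks (-log10 q strictly > 100), merge replicate peak sets, blacklist
against heterochromatin (H3K9me3 peaks merged at gap 3000 bp), and build a
matched shuffled background covering the same number of regions and the
same number of bp at random loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    FragmentSet,
    GenomeLayout,
    count_overlaps,
    empty_intervals,
    make_intervals,
    merge_intervals,
    overlaps_any,
    sort_intervals,
    validate_intervals,
)

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "neglog10_q"]
PROVENANCES = ("called", "merged", "shuffled", "blacklist")


def _empty_peaks() -> pd.DataFrame:
    df = empty_intervals()
    df["summit"] = pd.Series([], dtype=np.int64)
    df["neglog10_q"] = pd.Series([], dtype=float)
    return df


@dataclass
class PeakSet:
    """Sorted scored peak intervals for one target."""

    target: str
    peaks: pd.DataFrame  # chrom, start, end, summit, neglog10_q
    provenance: str = "called"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        validate_intervals(self.peaks)
        self.peaks = sort_intervals(self.peaks)
        if len(self.peaks):
            bad = ~(
                (self.peaks["summit"] >= self.peaks["start"])
                & (self.peaks["summit"] < self.peaks["end"])
            )
            if bad.any():
                raise ValueError("peak summit outside its interval")

    def __len__(self) -> int:
        return len(self.peaks)

    def with_peaks(self, peaks: pd.DataFrame, provenance: str | None = None) -> "PeakSet":
        return PeakSet(self.target, peaks, provenance or self.provenance)


def filter_fragment_size(fragments: FragmentSet, max_len: int = 120) -> FragmentSet:
    """Keep fragments strictly shorter than *max_len* bp (TF-sized)."""
    frags = fragments.fragments
    keep = (frags["end"] - frags["start"]) < max_len
    return fragments.with_fragments(frags[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# substitute caller
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def call_peaks_poisson(
    fragments: FragmentSet | pd.DataFrame,
    layout: GenomeLayout,
    window: int = 150,
    local_lambda_windows: tuple[int, int] = (1_000, 10_000),
    q_threshold: float = 0.05,
    exclude_central: int = 5,
    target: str | None = None,
) -> PeakSet:
    """Local-Poisson window scan.

    Each *window*-bp tile's fragment count is tested against
    lambda = max(genome-wide, 1 kb-local, 10 kb-local) expected count;
    windows significant after BH at *q_threshold* are joined when adjacent,
    the summit is the maximum-coverage bp of the joined region, and the
    region's score is -log10 of its minimum q.

    Local expectations are flanking means: the *exclude_central* windows
    centred on the tested one are left out, so a narrow enrichment does not
    inflate its own background estimate (the convention treatment-only
    callers use), while broad elevated regions still raise the local
    lambda and are not fragmented into spurious narrow peaks.
    """
    frags = fragments.fragments if isinstance(fragments, FragmentSet) else fragments
    name = target or (fragments.target if isinstance(fragments, FragmentSet) else "peaks")
    if len(frags) == 0:
        return PeakSet(name, _empty_peaks())

    rows = []
    for chrom in layout.chroms:
        L = layout[chrom]
        n_win = L // window
        if n_win == 0:
            continue
        starts = np.arange(n_win, dtype=np.int64) * window
        wins = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window})
        counts = count_overlaps(wins, frags).astype(float)
        lam_genome = counts.mean()
        lams = [np.full(n_win, lam_genome)]
        ones = np.ones(n_win)
        excl = max(1, exclude_central)
        excl_sum = np.convolve(counts, np.ones(excl), mode="same")
        excl_n = np.convolve(ones, np.ones(excl), mode="same")
        for span in local_lambda_windows:
            k = max(excl + 2, span // window)
            span_sum = np.convolve(counts, np.ones(k), mode="same")
            span_n = np.convolve(ones, np.ones(k), mode="same")
            local = (span_sum - excl_sum) / np.maximum(span_n - excl_n, 1.0)
            lams.append(local)
        lam = np.maximum.reduce(lams)
        pvals = stats.poisson.sf(counts - 1, lam)  # P(X >= count)
        rows.append((chrom, starts, counts, pvals))
    if not rows:
        return PeakSet(name, _empty_peaks())

    all_p = np.concatenate([r[3] for r in rows])
    all_q = _bh_adjust(all_p)
    out_rows = []
    offset = 0
    frag_by_chrom = {c: sub for c, sub in frags.groupby("chrom", sort=False)}
    for chrom, starts, counts, _p in rows:
        q = all_q[offset : offset + len(starts)]
        offset += len(starts)
        sig = np.flatnonzero(q < q_threshold)
        if len(sig) == 0:
            continue
        breaks = np.flatnonzero(np.diff(sig) > 1) + 1
        for run in np.split(sig, breaks):
            s = int(starts[run[0]])
            e = int(starts[run[-1]]) + window
            min_q = float(np.clip(q[run].min(), 1e-300, None))
            summit = _summit(frag_by_chrom.get(chrom), s, e)
            out_rows.append((chrom, s, e, summit, -np.log10(min_q)))
    if not out_rows:
        return PeakSet(name, _empty_peaks())
    peaks = pd.DataFrame(out_rows, columns=PEAK_COLUMNS)
    peaks["start"] = peaks["start"].astype(np.int64)
    peaks["end"] = peaks["end"].astype(np.int64)
    peaks["summit"] = peaks["summit"].astype(np.int64)
    return PeakSet(name, peaks)


def _summit(frags: pd.DataFrame | None, start: int, end: int) -> int:
    """Maximum-coverage bp within [start, end); leftmost on ties."""
    if frags is None or len(frags) == 0:
        return start
    sub = frags[(frags["start"] < end) & (frags["end"] > start)]
    if len(sub) == 0:
        return start
    diff = np.zeros(end - start + 1)
    lo = np.clip(sub["start"].to_numpy() - start, 0, None)
    hi = np.clip(sub["end"].to_numpy() - start, None, end - start)
    np.add.at(diff, lo, 1.0)
    np.add.at(diff, hi, -1.0)
    cov = np.cumsum(diff[:-1])
    return start + int(np.argmax(cov))


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def filter_high_confidence(peakset: PeakSet, min_neglog10_q: float = 100.0) -> PeakSet:
    """Keep peaks with -log10(q) strictly greater than the threshold."""
    keep = peakset.peaks["neglog10_q"] > min_neglog10_q
    return peakset.with_peaks(peakset.peaks[keep].reset_index(drop=True))


def merge_replicate_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Union of two replicate peak sets, merged where overlapping/bookended;
    the merged peak takes the maximum score and its carrier's summit."""
    if a.target != b.target:
        raise ValueError(f"targets differ: {a.target!r} vs {b.target!r}")
    combined = pd.concat([a.peaks, b.peaks], ignore_index=True)
    if len(combined) == 0:
        return PeakSet(a.target, _empty_peaks(), "merged")
    merged = merge_intervals(combined, max_gap=0)
    # map each constituent to its merged cluster, then take the max-q carrier
    hit = []
    for row in merged.itertuples(index=True):
        inside = combined[
            (combined["chrom"] == row.chrom)
            & (combined["start"] >= row.start)
            & (combined["end"] <= row.end)
        ]
        best = inside.loc[inside["neglog10_q"].idxmax()]
        hit.append((row.chrom, row.start, row.end, int(best["summit"]), float(best["neglog10_q"])))
    peaks = pd.DataFrame(hit, columns=PEAK_COLUMNS)
    peaks["start"] = peaks["start"].astype(np.int64)
    peaks["end"] = peaks["end"].astype(np.int64)
    peaks["summit"] = peaks["summit"].astype(np.int64)
    return PeakSet(a.target, peaks, "merged")


def build_blacklist(
    h3k9me3_peaks: PeakSet,
    extra_regions: pd.DataFrame | None = None,
    min_neglog10_q: float = 100.0,
    merge_gap: int = 3_000,
) -> pd.DataFrame:
    """Heterochromatin blacklist: high-confidence H3K9me3 peaks merged at
    gap 3000 bp, unioned with any extra (assembly-specific) regions."""
    confident = filter_high_confidence(h3k9me3_peaks, min_neglog10_q).peaks
    merged = merge_intervals(confident[["chrom", "start", "end"]], max_gap=merge_gap) if len(confident) else empty_intervals()
    if extra_regions is not None and len(extra_regions):
        merged = merge_intervals(
            pd.concat([merged, extra_regions[["chrom", "start", "end"]]], ignore_index=True),
            max_gap=0,
        )
    return merged


def apply_blacklist(peakset: PeakSet, blacklist: pd.DataFrame) -> PeakSet:
    """Remove peaks overlapping any blacklist region by >= 1 bp."""
    if len(blacklist) == 0 or len(peakset) == 0:
        return peakset.with_peaks(peakset.peaks.copy())
    keep = ~overlaps_any(peakset.peaks, blacklist)
    return peakset.with_peaks(peakset.peaks[keep].reset_index(drop=True))


def shuffle_peaks(
    peakset: PeakSet,
    layout: GenomeLayout,
    exclude_regions: pd.DataFrame | None = None,
    seed: int = 0,
    max_retries: int = 1_000,
) -> PeakSet:
    """Matched random background: same number of regions with identical
    per-region lengths (hence the same total bp), uniformly placed outside
    *exclude_regions*, non-overlapping among themselves; chromosome
    reassignment is allowed.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    lengths = (peakset.peaks["end"] - peakset.peaks["start"]).to_numpy()
    chroms = layout.chroms
    weights = np.array([layout[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    exclude = (
        merge_intervals(exclude_regions[["chrom", "start", "end"]])
        if exclude_regions is not None and len(exclude_regions)
        else empty_intervals()
    )
    placed: list[tuple[str, int, int]] = []
    for length in lengths:
        blocked = exclude
        if placed:
            blocked = pd.concat(
                [exclude, pd.DataFrame(placed, columns=["chrom", "start", "end"])],
                ignore_index=True,
            )
        for _ in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            hi = layout[chrom] - int(length)
            if hi <= 0:
                continue
            start = int(rng.integers(0, hi + 1))
            cand = make_intervals([chrom], [start], [start + int(length)])
            if not overlaps_any(cand, blocked)[0]:
                placed.append((chrom, start, start + int(length)))
                break
        else:
            raise RuntimeError(
                f"could not place a {length} bp shuffled region after {max_retries} tries"
            )
    if not placed:
        return PeakSet(peakset.target, _empty_peaks(), "shuffled")
    peaks = pd.DataFrame(placed, columns=["chrom", "start", "end"])
    peaks["start"] = peaks["start"].astype(np.int64)
    peaks["end"] = peaks["end"].astype(np.int64)
    peaks["summit"] = (peaks["start"] + peaks["end"]) // 2
    peaks["neglog10_q"] = 0.0
    return PeakSet(peakset.target, peaks, "shuffled")
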