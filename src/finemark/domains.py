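"""Broad-domain (island) calling and coverage-ratio comparison.

Islands are called SICER-style: the genome is tiled in fixed windows
(default 500 bp), the expected background count per window is
``lambda = total_fragments * w / (egf * genome_length)`` with *egf* the
effective (mappable) genome fraction, a window is *eligible* iff its count
reaches the smallest integer whose Poisson upper-tail probability falls
below the window significance threshold, and eligible windows separated by
at most *gap* bp cluster into one island.  The island score is the summed
Poisson surprisal, ``sum(-ln P(count; lambda))`` over its eligible windows
(units: nats).  Fragments are counted at their full extent with no shift.

Downstream, domains are the islands with score strictly > 500 and length
strictly > 3 kb, merged within 10 kb and between replicates (filter first,
then merge — merging never rescues a sub-threshold island).  The
coverage-ratio comparison contrasts mean reads/bp of broad domains against
narrow peaks lying outside them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FragmentSet, GenomeLayout, count_overlaps, overlaps_any


def _eligibility_threshold(lam: float, window_p: float) -> int:
    """Smallest integer count c with P(Poisson(lam) >= c) < window_p."""
    c = int(stats.poisson.ppf(1.0 - window_p, lam))
    while stats.poisson.sf(c - 1, lam) >= window_p:
        c += 1
    while c > 1 and stats.poisson.sf(c - 2, lam) < window_p:
        c -= 1
    return c


def call_islands(
    fragments: FragmentSet | pd.DataFrame,
    layout: GenomeLayout,
    w: int = 500,
    gap: int = 2_000,
    egf: float = 0.7,
    window_p: float = 0.2,
) -> pd.DataFrame:
    """Cluster significantly enriched fixed windows into scored islands.

    Returns a frame with chrom, start, end, score (nats) and
    ``n_eligible_windows``; the interval spans the first to last eligible
    window of the cluster.  Only full *w*-bp windows are tiled (a terminal
    partial window is not tested).
    """
    frags = fragments.fragments if isinstance(fragments, FragmentSet) else fragments
    total = len(frags)
    lam = total * w / (egf * layout.total_length)
    if lam <= 0:
        raise ValueError("zero expected count: no fragments (or empty genome)")
    threshold = _eligibility_threshold(lam, window_p)

    rows = []
    for chrom in layout.chroms:
        n_win = layout[chrom] // w
        if n_win == 0:
            continue
        starts = np.arange(n_win, dtype=np.int64) * w
        wins = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + w})
        counts = count_overlaps(wins, frags)
        eligible = np.flatnonzero(counts >= threshold)
        if len(eligible) == 0:
            continue
        # consecutive eligible windows with inter-window gap <= `gap` cluster
        max_skip = gap // w  # number of ineligible windows allowed between
        breaks = np.flatnonzero(np.diff(eligible) > max_skip + 1) + 1
        for run in np.split(eligible, breaks):
            cts = counts[run]
            score = float(np.sum(-stats.poisson.logpmf(cts, lam)))
            rows.append(
                (chrom, int(starts[run[0]]), int(starts[run[-1]]) + w, score, len(run))
            )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_eligible_windows"])
    if len(out):
        out["start"] = out["start"].astype(np.int64)
        out["end"] = out["end"].astype(np.int64)
    return out


def filter_domains(
    islands: pd.DataFrame, min_score: float = 500.0, min_length: int = 3_000
) -> pd.DataFrame:
    """Keep islands with score strictly > *min_score* and length strictly
    > *min_length* bp."""
    if len(islands) == 0:
        return islands.copy()
    length = islands["end"] - islands["start"]
    keep = (islands["score"] > min_score) & (length > min_length)
    return islands[keep].reset_index(drop=True)


def merge_domains(
    domains_rep1: pd.DataFrame, domains_rep2: pd.DataFrame, max_gap: int = 10_000
) -> pd.DataFrame:
    """Union of both replicates' domains merged at gap <= *max_gap* bp;
    merged score = sum of constituent scores."""
    combined = pd.concat([domains_rep1, domains_rep2], ignore_index=True)
    if len(combined) == 0:
        return pd.DataFrame({"chrom": [], "start": [], "end": [], "score": []})
    combined = combined.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = []
    for chrom, sub in combined.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        scores = sub["score"].to_numpy() if "score" in sub.columns else np.zeros(len(sub))
        breaks = np.flatnonzero(starts[1:] > ends[:-1] + max_gap) + 1
        run_start = np.concatenate(([0], breaks))
        run_end = np.concatenate((breaks, [len(sub)]))
        for a, b in zip(run_start, run_end):
            rows.append((chrom, int(starts[a]), int(ends[b - 1]), float(scores[a:b].sum())))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def region_coverage(
    replicate_fragments: list[FragmentSet | pd.DataFrame], regions: pd.DataFrame
) -> pd.DataFrame:
    """Per-region mean read count across replicates and reads/bp coverage."""
    if not replicate_fragments:
        raise ValueError("need at least one replicate")
    if len(regions) == 0:
        raise ValueError("empty region set")
    counts = np.zeros(len(regions), dtype=float)
    for fs in replicate_fragments:
        frags = fs.fragments if isinstance(fs, FragmentSet) else fs
        counts += count_overlaps(regions, frags)
    reads = counts / len(replicate_fragments)
    out = regions[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["length"] = out["end"] - out["start"]
    out["reads"] = reads
    out["coverage"] = reads / out["length"]
    return out


def peaks_outside_domains(peaks: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Peaks not overlapping any domain by >= 1 bp."""
    if len(domains) == 0:
        return peaks.reset_index(drop=True)
    keep = ~overlaps_any(peaks, domains[["chrom", "start", "end"]])
    return peaks[keep].reset_index(drop=True)


def coverage_ratio(
    peak_coverages: pd.DataFrame, domain_coverages: pd.DataFrame
) -> float:
    """Mean domain coverage over mean peak coverage (reads/bp ratio).

    Callers must pass peaks already restricted to those outside domains
    (see :func:`peaks_outside_domains`); an empty set after that exclusion
    is an error, not a ratio.
    """
    if len(peak_coverages) == 0 or len(domain_coverages) == 0:
        raise ValueError("both coverage sets must be non-empty")
    return float(domain_coverages["coverage"].mean() / peak_coverages["coverage"].mean())
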