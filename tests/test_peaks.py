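import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finemark.genome import FragmentSet, GenomeLayout, make_intervals, overlaps_any
from finemark.peaks import (
    PeakSet,
    apply_blacklist,
    build_blacklist,
    call_peaks_poisson,
    filter_fragment_size,
    filter_high_confidence,
    merge_replicate_peaks,
    shuffle_peaks,
)


def _fragset(chroms, starts, ends, target="tf"):
    return FragmentSet("s1", "control", 1, target, make_intervals(chroms, starts, ends))


def _peakset(rows, target="tf", provenance="called"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "neglog10_q"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["summit"] = df["summit"].astype(np.int64)
    return PeakSet(target, df, provenance)


class TestFragmentSizeFilter:
    def test_strictly_less_than_120(self):
        fs = _fragset(["c"] * 4, [0, 0, 0, 0], [100, 119, 120, 150])
        kept = filter_fragment_size(fs)
        assert sorted(kept.lengths.tolist()) == [100, 119]

    def test_all_long_gives_empty(self):
        fs = _fragset(["c"] * 2, [0, 10], [200, 300])
        assert len(filter_fragment_size(fs)) == 0

    def test_matches_bruteforce(self, rng):
        starts = rng.integers(0, 10_000, 200)
        lengths = rng.integers(50, 200, 200)
        fs = _fragset(["c"] * 200, starts, starts + lengths)
        kept = filter_fragment_size(fs, 120)
        assert len(kept) == int((lengths < 120).sum())


class TestCaller:
    def test_empty_fragments_give_empty_peakset(self, tiny_layout):
        fs = _fragset([], [], [])
        assert len(call_peaks_poisson(fs, tiny_layout)) == 0

    def test_planted_spike_recovered_with_summit_inside(self, rng):
        layout = GenomeLayout({"c": 1_000_000})
        n_bg = 20_000  # flat background, ~0.02 starts/bp
        bg_starts = rng.integers(0, 999_800, n_bg)
        spike_starts = rng.integers(600_000, 600_500, 400)  # 20x in 500 bp
        starts = np.concatenate([bg_starts, spike_starts])
        fs = _fragset(["c"] * len(starts), starts, starts + 80)
        ps = call_peaks_poisson(fs, layout)
        hits = ps.peaks[(ps.peaks["end"] > 600_000) & (ps.peaks["start"] < 600_500)]
        assert len(hits) == 1
        assert 600_000 <= hits.iloc[0]["summit"] < 600_500 + 80
        # and nothing called away from the spike
        assert len(ps) == 1

    def test_false_discovery_controlled_on_flat_background(self, rng):
        layout = GenomeLayout({"c": 500_000})
        false_runs = 0
        n_runs = 10
        for _ in range(n_runs):
            starts = rng.integers(0, 499_800, 10_000)
            fs = _fragset(["c"] * 10_000, starts, starts + 80)
            false_runs += int(len(call_peaks_poisson(fs, layout)) > 0)
        # BH at q<0.05 over the whole scan: most null runs are clean
        assert false_runs <= 2


class TestPostProcessing:
    def test_high_confidence_is_strict(self):
        ps = _peakset([("c", 0, 100, 50, 99.0), ("c", 200, 300, 250, 100.0), ("c", 400, 500, 450, 101.0)])
        kept = filter_high_confidence(ps, 100)
        assert kept.peaks["neglog10_q"].tolist() == [101.0]

    def test_merge_takes_max_score_and_its_summit(self):
        a = _peakset([("c", 0, 100, 10, 150.0)])
        b = _peakset([("c", 50, 200, 180, 200.0)])
        merged = merge_replicate_peaks(a, b)
        assert len(merged) == 1
        row = merged.peaks.iloc[0]
        assert (row["start"], row["end"]) == (0, 200)
        assert row["neglog10_q"] == 200.0
        assert row["summit"] == 180

    def test_merge_disjoint_is_sorted_union(self):
        a = _peakset([("c", 500, 600, 550, 10.0)])
        b = _peakset([("c", 0, 100, 50, 20.0)])
        merged = merge_replicate_peaks(a, b)
        assert merged.peaks["start"].tolist() == [0, 500]

    def test_merge_identical_is_idempotent(self):
        a = _peakset([("c", 0, 100, 50, 10.0), ("c", 300, 400, 350, 20.0)])
        merged = merge_replicate_peaks(a, a)
        pd.testing.assert_frame_equal(merged.peaks, a.peaks)

    def test_blacklist_merges_within_3kb_only(self):
        near = _peakset(
            [("c", 0, 1000, 500, 150.0), ("c", 3000, 4000, 3500, 150.0)], target="H3K9me3"
        )
        bl = build_blacklist(near)
        assert len(bl) == 1 and bl.iloc[0]["end"] == 4000
        far = _peakset(
            [("c", 0, 1000, 500, 150.0), ("c", 5100, 6000, 5500, 150.0)], target="H3K9me3"
        )
        assert len(build_blacklist(far)) == 2

    def test_blacklist_drops_low_confidence_first(self):
        ps = _peakset([("c", 0, 1000, 500, 50.0)], target="H3K9me3")
        assert len(build_blacklist(ps)) == 0

    def test_apply_blacklist_boundary(self):
        ps = _peakset([("c", 0, 100, 50, 10.0), ("c", 100, 200, 150, 10.0)])
        bl = make_intervals(["c"], [0], [100])
        kept = apply_blacklist(ps, bl)
        # abutting peak (no 1 bp overlap) survives
        assert kept.peaks["start"].tolist() == [100]

    def test_filters_commute(self, rng):
        rows = [
            ("c", int(s), int(s) + 100, int(s) + 50, float(q))
            for s, q in zip(rng.integers(0, 50_000, 40) * 2, rng.uniform(50, 150, 40))
        ]
        ps = _peakset(rows)
        bl = make_intervals(["c"], [10_000], [30_000])
        one = filter_high_confidence(apply_blacklist(ps, bl), 100).peaks
        other = apply_blacklist(filter_high_confidence(ps, 100), bl).peaks
        pd.testing.assert_frame_equal(one, other)


class TestShuffle:
    def _base(self):
        return _peakset(
            [("c", 0, 1000, 500, 10.0), ("c", 5000, 5300, 5100, 10.0), ("c", 9000, 9800, 9400, 10.0)]
        )

    def test_preserves_count_and_length_multiset(self, layout):
        ps = self._base()
        shuf = shuffle_peaks(ps, layout, seed=1)
        lengths = sorted((shuf.peaks["end"] - shuf.peaks["start"]).tolist())
        assert lengths == [300, 800, 1000]
        assert shuf.provenance == "shuffled"

    def test_deterministic_per_seed(self, layout):
        ps = self._base()
        a = shuffle_peaks(ps, layout, seed=7).peaks
        b = shuffle_peaks(ps, layout, seed=7).peaks
        pd.testing.assert_frame_equal(a, b)
        c = shuffle_peaks(ps, layout, seed=8).peaks
        assert not a[["start"]].equals(c[["start"]])

    def test_respects_exclusions_and_self_overlap(self, layout):
        ps = self._base()
        exclude = make_intervals(["chr1", "chr2"], [0, 0], [900_000, 500_000])
        shuf = shuffle_peaks(ps, layout, exclude_regions=exclude, seed=3)
        assert not overlaps_any(shuf.peaks, exclude).any()
        s = shuf.peaks.sort_values(["chrom", "start"])
        same = s["chrom"].to_numpy()[1:] == s["chrom"].to_numpy()[:-1]
        assert not (same & (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1])).any()

    def test_infeasible_placement_raises(self):
        layout = GenomeLayout({"c": 1_500})
        ps = _peakset([("c", 0, 1_000, 500, 1.0)])
        exclude = make_intervals(["c"], [0], [1_400])
        with pytest.raises(RuntimeError):
            shuffle_peaks(ps, layout, exclude_regions=exclude, seed=1, max_retries=50)

    def test_uniform_start_positions(self):
        """1000 shuffles of one 1 kb peak on a 1 Mb genome: starts uniform."""
        layout = GenomeLayout({"c": 1_000_000})
        ps = _peakset([("c", 0, 1000, 500, 1.0)])
        starts = [
            int(shuffle_peaks(ps, layout, seed=s).peaks.iloc[0]["start"]) for s in range(1000)
        ]
        counts, _ = np.histogram(starts, bins=10, range=(0, 999_001))
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.01
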