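import subprocess

import numpy as np
import pandas as pd
import pytest

from finemark.coverage import (
    BinnedTrack,
    NormalizationResult,
    compute_coverage,
    count_in_regions,
    final_scale_factor,
    merge_replicates,
    normalize_samples,
    read_bedgraph,
    tmm_factors,
    to_rpkm,
    write_bedgraph,
    zscore_normalize,
)
from finemark.genome import GenomeLayout, make_intervals
from conftest import brute_force_overlap_counts


class TestComputeCoverage:
    def test_single_fragment_hits_every_overlapped_bin(self, tiny_layout):
        frags = make_intervals(["chrT"], [0], [25])
        track = compute_coverage(frags, tiny_layout, bin_size=10)
        np.testing.assert_array_equal(track.values["chrT"][:4], [1, 1, 1, 0])

    def test_duplicates_counted_once_with_dedup(self, tiny_layout):
        frags = make_intervals(["chrT", "chrT"], [100, 100], [200, 200])
        assert compute_coverage(frags, tiny_layout, 50, dedup=True).values["chrT"].max() == 1
        assert compute_coverage(frags, tiny_layout, 50, dedup=False).values["chrT"].max() == 2

    def test_max_fragment_length_filter(self, tiny_layout):
        frags = make_intervals(["chrT", "chrT"], [0, 500], [100, 700])
        track = compute_coverage(frags, tiny_layout, 100, max_fragment_length=120)
        assert track.values["chrT"][0] == 1  # 100 bp kept
        assert track.values["chrT"][5] == 0  # 200 bp excluded

    def test_matches_bruteforce_bin_counts(self, rng, tiny_layout):
        starts = rng.integers(0, 9_500, size=1000)
        frags = make_intervals(["chrT"] * 1000, starts, starts + rng.integers(1, 400, 1000))
        track = compute_coverage(frags, tiny_layout, bin_size=100)
        bins = make_intervals(
            ["chrT"] * 100, np.arange(100) * 100, np.arange(100) * 100 + 100
        )
        np.testing.assert_array_equal(
            track.values["chrT"], brute_force_overlap_counts(bins, frags)
        )


class TestRpkm:
    def test_arithmetic(self, tiny_layout):
        track = compute_coverage(make_intervals(["chrT"], [0], [10]), tiny_layout, 10)
        rpkm = to_rpkm(track, 10**6)
        assert rpkm.values["chrT"][0] == pytest.approx(100.0)  # 1e9/(10*1e6)

    def test_doubling_depth_halves_values(self, tiny_layout):
        frags = make_intervals(["chrT"] * 3, [0, 100, 200], [50, 150, 250])
        t = compute_coverage(frags, tiny_layout, 10)
        a = to_rpkm(t, 1000).all_values()
        b = to_rpkm(t, 2000).all_values()
        np.testing.assert_allclose(a, 2 * b)

    def test_requires_positive_total(self, tiny_layout):
        t = compute_coverage(make_intervals([], [], []), tiny_layout, 10)
        with pytest.raises(ValueError):
            to_rpkm(t, 0)

    def test_state_transition_enforced(self, tiny_layout):
        t = compute_coverage(make_intervals(["chrT"], [0], [10]), tiny_layout, 10)
        r = to_rpkm(t, 100)
        with pytest.raises(ValueError):
            to_rpkm(r, 100)


class TestMergeAndZscore:
    def test_merge_is_per_bin_mean(self, tiny_layout):
        a = BinnedTrack(tiny_layout, 100, {"chrT": np.full(100, 2.0)})
        b = BinnedTrack(tiny_layout, 100, {"chrT": np.full(100, 4.0)})
        assert merge_replicates([a, b]).values["chrT"][0] == 3.0

    def test_merge_rejects_mismatched_grids(self, tiny_layout):
        a = BinnedTrack(tiny_layout, 100, {"chrT": np.zeros(100)})
        b = BinnedTrack(tiny_layout, 50, {"chrT": np.zeros(200)})
        with pytest.raises(ValueError):
            merge_replicates([a, b])

    def test_zscore_small_example(self):
        layout = GenomeLayout({"c": 30})
        t = BinnedTrack(layout, 10, {"c": np.array([1.0, 2.0, 3.0])})
        z = zscore_normalize(t)
        np.testing.assert_allclose(
            z.values["c"], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_zscore_output_standardized(self, rng, tiny_layout):
        t = BinnedTrack(tiny_layout, 100, {"chrT": rng.gamma(2.0, 3.0, size=100)})
        flat = zscore_normalize(t).all_values()
        assert abs(flat.mean()) < 1e-9
        assert abs(flat.std() - 1.0) < 1e-9

    def test_constant_track_becomes_zero_with_warning(self, tiny_layout):
        t = BinnedTrack(tiny_layout, 100, {"chrT": np.full(100, 5.0)})
        with pytest.warns(UserWarning):
            z = zscore_normalize(t)
        assert (z.all_values() == 0).all()

    def test_zscore_idempotent_in_value(self, rng, tiny_layout):
        t = BinnedTrack(tiny_layout, 100, {"chrT": rng.poisson(10, size=100).astype(float)})
        z1 = zscore_normalize(t)
        z2 = BinnedTrack(tiny_layout, 100, {"chrT": z1.values["chrT"].copy()}, "rpkm")
        # already-standardized values are a fixed point (up to fp noise)
        np.testing.assert_allclose(
            zscore_normalize(z2).all_values(), z1.all_values(), atol=1e-9
        )


class TestCountInRegions:
    def test_spanning_fragment_counts_once_per_region(self):
        regions = make_intervals(["c", "c"], [0, 100], [100, 200])
        frags = make_intervals(["c"], [50, ], [150])
        np.testing.assert_array_equal(count_in_regions(frags, regions), [1, 1])

    def test_matches_bruteforce(self, rng):
        f_starts = rng.integers(0, 50_000, 500)
        frags = make_intervals(["c"] * 500, f_starts, f_starts + rng.integers(1, 400, 500))
        r_starts = rng.integers(0, 50_000, 20)
        regions = make_intervals(["c"] * 20, r_starts, r_starts + rng.integers(200, 3000, 20))
        np.testing.assert_array_equal(
            count_in_regions(frags, regions), brute_force_overlap_counts(regions, frags)
        )


def bruteforce_tmm(X: np.ndarray) -> np.ndarray:
    """Independent TMM oracle, written directly from the definition with
    plain loops: M/A over doubly-positive regions, 30%/5% two-tailed trims
    by rank, delta-method weights, geometric-mean-1 rescale."""
    n_samp = X.shape[1]
    lib = X.sum(axis=0)
    uq = np.array([np.quantile(X[:, k], 0.75) / lib[k] for k in range(n_samp)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for k in range(n_samp):
        if k == ref:
            factors.append(1.0)
            continue
        M, A, W = [], [], []
        for i in range(X.shape[0]):
            y, r = X[i, k], X[i, ref]
            if y > 0 and r > 0:
                obs, rf = y / lib[k], r / lib[ref]
                M.append(np.log2(obs / rf))
                A.append(0.5 * (np.log2(obs) + np.log2(rf)))
                W.append(1.0 / ((lib[k] - y) / (lib[k] * y) + (lib[ref] - r) / (lib[ref] * r)))
        M, A, W = np.array(M), np.array(A), np.array(W)
        if len(M) == 0 or np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        loM, hiM = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        loA, hiA = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        f = np.sum(W[keep] * M[keep]) / np.sum(W[keep])
        factors.append(2.0**f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        X = np.tile(np.arange(1, 101)[:, None], (1, 2)).astype(float)
        np.testing.assert_allclose(tmm_factors(X), [1.0, 1.0])

    def test_pure_depth_difference_absorbed(self, rng):
        a = rng.poisson(50, size=500).astype(float) + 1
        X = np.column_stack([a, 2 * a])
        np.testing.assert_allclose(tmm_factors(X), [1.0, 1.0])

    def test_matches_bruteforce_oracle_with_composition_bias(self, rng):
        X = rng.negative_binomial(5, 0.02, size=(2000, 4)).astype(float)
        bias = rng.choice(2000, 200, replace=False)
        X[bias, 1] *= 4  # sample 1 composition-inflated
        mine = tmm_factors(X)
        oracle = bruteforce_tmm(X)
        np.testing.assert_allclose(mine, oracle, atol=1e-6)
        # the inflated sample's library size is overstated by the biased
        # regions, so the majority log-ratios go negative: factor < 1
        assert mine[1] < 1.0

    def test_matches_edger_reference_implementation(self, rng, tmp_path):
        """Cross-check against edgeR's calcNormFactors via Rscript."""
        X = rng.negative_binomial(8, 0.01, size=(800, 3)).astype(float)
        X[rng.choice(800, 60, replace=False), 2] *= 3
        path = tmp_path / "m.tsv"
        np.savetxt(path, X, delimiter="\t", fmt="%d")
        out = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR)); '
             f'x <- as.matrix(read.table("{path}")); '
             f'cat(calcNormFactors(x, method="TMM"), sep="\\n")'],
            capture_output=True, text=True, timeout=120,
        )
        assert out.returncode == 0, out.stderr
        reference = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(tmm_factors(X), reference, atol=1e-6)

    def test_too_few_usable_regions_warns_and_returns_one(self):
        X = np.array([[5.0, 0.0], [0.0, 7.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            f = tmm_factors(X)
        np.testing.assert_allclose(f, [1.0, 1.0])


class TestFinalScale:
    @pytest.mark.parametrize(
        "tmm,rip,expect",
        [(1.25, 800_000, 1.0), (1.0, 10**6, 1.0), (0.8, 2_500_000, 0.5)],
    )
    def test_formula(self, tmm, rip, expect):
        assert final_scale_factor(tmm, rip) == pytest.approx(expect)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            final_scale_factor(0.0, 100)
        with pytest.raises(ValueError):
            final_scale_factor(1.0, 0)

    def test_normalization_result_consistency(self):
        n = NormalizationResult("s1", 1.25, 800_000)
        assert n.final_scale == pytest.approx(1_000_000 / (1.25 * 800_000))

    def test_normalize_samples_names_and_rips(self, rng):
        X = pd.DataFrame(
            rng.poisson(40, size=(300, 2)).astype(float) + 1, columns=["a", "b"]
        )
        norms = normalize_samples(X)
        assert [n.sample_id for n in norms] == ["a", "b"]
        assert norms[0].reads_in_peaks == int(X["a"].sum())


class TestBedgraph:
    def test_roundtrip(self, rng, tiny_layout):
        t = BinnedTrack(tiny_layout, 100, {"chrT": rng.poisson(3, 100).astype(float)})
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "t.bedgraph")
            write_bedgraph(t, p)
            back = read_bedgraph(p, tiny_layout, 100)
        np.testing.assert_array_equal(back.values["chrT"], t.values["chrT"])
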