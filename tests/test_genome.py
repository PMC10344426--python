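import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from finemark.genome import (
    BedFormatError,
    GenomeLayout,
    IntervalError,
    count_overlaps,
    make_intervals,
    merge_intervals,
    overlaps_any,
    read_bed,
    read_gene_annotation,
    total_bp,
    write_bed,
)
from conftest import brute_force_overlap_counts


class TestLayout:
    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(IntervalError):
            GenomeLayout({"chr1": 0})

    def test_chrom_sizes_roundtrip(self, layout, tmp_path):
        path = tmp_path / "genome.chrom.sizes"
        layout.to_file(path)
        again = GenomeLayout.from_file(path)
        assert dict(again.lengths) == dict(layout.lengths)


class TestBedIO:
    def test_basic_three_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        df = read_bed(p)
        assert len(df) == 1
        assert (df.loc[0, "chrom"], df.loc[0, "start"], df.loc[0, "end"]) == ("chr1", 0, 100)

    def test_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(IntervalError, match="line 1"):
            read_bed(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\tnot_an_int\t200\n")
        with pytest.raises(BedFormatError, match="line 2"):
            read_bed(p)

    def test_mixed_column_file_carries_score(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t200\t300\tpk\t250\nchr1\t400\t500\n")
        df = read_bed(p)
        assert len(df) == 3
        assert df.loc[1, "score"] == 250.0
        assert np.isnan(df.loc[0, "score"])

    def test_out_of_layout_interval_rejected(self, tmp_path, tiny_layout):
        p = tmp_path / "a.bed"
        p.write_text("chrT\t9000\t11000\n")
        with pytest.raises(IntervalError):
            read_bed(p, tiny_layout)

    def test_write_empty_set_gives_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        write_bed(make_intervals([], [], []), p)
        assert p.read_text() == ""

    def test_roundtrip_random_intervals(self, tmp_path, random_intervals, rng):
        df = random_intervals.copy()
        df["name"] = [f"iv{i}" for i in range(len(df))]
        df["score"] = rng.normal(size=len(df))
        p = tmp_path / "rt.bed"
        write_bed(df, p)
        back = read_bed(p)
        pd.testing.assert_frame_equal(back, df)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 500)), min_size=0, max_size=30))
    def test_roundtrip_property(self, tmp_path_factory, pairs):
        df = make_intervals(
            ["chrH"] * len(pairs), [s for s, _ in pairs], [s + w for s, w in pairs]
        )
        p = tmp_path_factory.mktemp("bed") / "x.bed"
        write_bed(df, p)
        pd.testing.assert_frame_equal(read_bed(p), df)


class TestGeneAnnotation:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=gA\n"
        "chr1\tsrc\tgene\t3001\t4000\t.\t-\t.\tID=gB\n"
        "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=gA\n"
        "chr2\tsrc\tgene\t501\t900\t.\t+\t.\tID=gC\n"
        "chr2\tsrc\tgene\t2001\t2500\t.\t-\t.\tID=gD\n"
        "chr2\tsrc\tgene\t5001\t5600\t.\t+\t.\tID=gE\n"
    )

    def test_gff3_parse_and_tss_convention(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(self.GFF)
        ann = read_gene_annotation(p, "gff3")
        assert len(ann) == 5
        assert set(ann.genes["gene_id"]) == {"gA", "gB", "gC", "gD", "gE"}
        ga = ann.genes.set_index("gene_id")
        # plus strand: tss = 0-based start; minus strand: tss = end - 1
        assert ga.loc["gA", "tss"] == 1000
        assert ga.loc["gB", "tss"] == 3999
        assert len(ann.exons) == 1

    def test_missing_strand_rejected(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text("chr1\tsrc\tgene\t1\t100\t.\t.\t.\tID=gX\n")
        with pytest.raises(BedFormatError):
            read_gene_annotation(p, "gff3")

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=gX\n"
            "chr1\tsrc\tgene\t201\t300\t.\t+\t.\tID=gX\n"
        )
        with pytest.raises(BedFormatError, match="duplicate"):
            read_gene_annotation(p, "gff3")

    def test_bed6_gene_annotation(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t1000\t2000\tgA\t0\t+\nchr1\t3000\t4000\tgB\t0\t-\n")
        ann = read_gene_annotation(p, "bed")
        ga = ann.genes.set_index("gene_id")
        assert ga.loc["gA", "tss"] == 1000
        assert ga.loc["gB", "tss"] == 3999


def brute_force_merge(df: pd.DataFrame, max_gap: int) -> set[tuple]:
    """O(n^2) union-with-gap oracle: repeatedly fuse any two intervals whose
    gap is <= max_gap until a fixed point."""
    items = [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples(index=False)]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and si <= ej + max_gap and sj <= ei + max_gap:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return set(items)


class TestMergeIntervals:
    def test_bookended_merge_at_gap_zero(self):
        df = make_intervals(["c", "c"], [0, 100], [100, 200])
        out = merge_intervals(df, 0)
        assert out.to_records(index=False).tolist() == [("c", 0, 200)]

    def test_distance_3000_merges(self):
        # bedtools merge -d 3000 semantics: gap of exactly 3000 bp merges
        df = make_intervals(["c", "c"], [0, 3100], [100, 3200])
        out = merge_intervals(df, 3000)
        assert out.to_records(index=False).tolist() == [("c", 0, 3200)]
        out2 = merge_intervals(make_intervals(["c", "c"], [0, 3101], [100, 3201]), 3000)
        assert len(out2) == 2

    @pytest.mark.parametrize("max_gap", [0, 50, 3000])
    def test_matches_pairwise_oracle(self, rng, max_gap):
        starts = rng.integers(0, 50_000, size=50)
        widths = rng.integers(1, 4_000, size=50)
        chroms = rng.choice(["c1", "c2"], size=50)
        df = make_intervals(chroms, starts, starts + widths)
        got = merge_intervals(df, max_gap)
        assert set(got.to_records(index=False).tolist()) == brute_force_merge(df, max_gap)

    def test_idempotent(self, random_intervals):
        once = merge_intervals(random_intervals, 500)
        twice = merge_intervals(once, 500)
        pd.testing.assert_frame_equal(once, twice)

    def test_covered_bp_never_decreases(self, random_intervals):
        assert total_bp(merge_intervals(random_intervals, 1000)) >= total_bp(random_intervals)


class TestOverlapPrimitives:
    def test_count_overlaps_matches_bruteforce(self, rng):
        q_starts = rng.integers(0, 20_000, size=60)
        s_starts = rng.integers(0, 20_000, size=200)
        queries = make_intervals(
            rng.choice(["c1", "c2"], 60), q_starts, q_starts + rng.integers(1, 800, 60)
        )
        subjects = make_intervals(
            rng.choice(["c1", "c2"], 200), s_starts, s_starts + rng.integers(1, 300, 200)
        )
        np.testing.assert_array_equal(
            count_overlaps(queries, subjects), brute_force_overlap_counts(queries, subjects)
        )

    def test_abutting_intervals_do_not_overlap(self):
        a = make_intervals(["c"], [0], [100])
        b = make_intervals(["c"], [100], [200])
        assert not overlaps_any(a, b)[0]
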