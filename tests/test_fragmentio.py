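"""Pairing/filtering, dyad trimming, coverage, length summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfdnafrag import (
    FragmentRecord,
    Region,
    build_coverage,
    length_histogram,
    mono_di_split,
    pair_and_filter,
    trim_fragments,
    trim_to_dyad,
)
from cfdnafrag.fragmentio import write_bedgraph, write_fragments_bed, read_fragments_bed

from .conftest import frame_from_intervals, make_pair, make_read


class TestPairAndFilter:
    def test_pair_coupled_to_outer_span(self):
        frags, dropped = pair_and_filter(make_pair("a", 100, 265))
        assert frags.iloc[0].tolist() == ["chr1", 100, 265, 165]
        assert sum(dropped.values()) == 0

    def test_insert_1001_dropped_1000_kept(self):
        alns = make_pair("long", 100, 1101) + make_pair("edge", 100, 1100)
        frags, dropped = pair_and_filter(alns)
        assert frags["length"].tolist() == [1000]
        assert dropped["too_long"] == 1

    def test_unpaired_counted(self):
        orphan = make_read("solo", 500, 0, 97)  # mate never appears
        unpaired_flagged = make_read("np", 600, 0, 0)  # not paired at all
        frags, dropped = pair_and_filter([orphan, unpaired_flagged])
        assert len(frags) == 0
        assert dropped["unpaired"] == 2

    def test_secondary_dropped(self):
        reads = make_pair("ok", 100, 400)
        sec = make_read("ok2", 150, 300, 99 | 256)
        frags, dropped = pair_and_filter(reads + [sec])
        assert len(frags) == 1
        assert dropped["secondary"] == 1

    def test_conservation_of_input_pairs(self):
        alns = (make_pair("a", 100, 300) + make_pair("b", 200, 1300)
                + [make_read("c", 900, 0, 97)])
        frags, dropped = pair_and_filter(alns)
        # kept pairs + dropped reasons account for every pair/read
        assert len(frags) + dropped["too_long"] == 2
        assert dropped["unpaired"] == 1


class TestTrimToDyad:
    def test_length_165_example(self):
        t = trim_to_dyad(FragmentRecord("chr1", 100, 265))
        assert (t.dyad, t.start, t.end) == (182, 142, 222)

    def test_idempotent_on_80bp(self):
        t = trim_to_dyad(FragmentRecord("chr1", 0, 80))
        assert (t.start, t.end) == (0, 80)

    @given(st.integers(min_value=80, max_value=1000), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_output_always_80bp(self, length, start):
        t = trim_to_dyad(FragmentRecord("chr1", start, start + length))
        assert t.end - t.start == 80
        assert t.dyad == start + length // 2

    def test_short_fragment_rejected(self):
        with pytest.raises(ValueError, match="cannot be trimmed"):
            trim_to_dyad(FragmentRecord("chr1", 0, 79))

    def test_bulk_trim_drops_short(self):
        frags = frame_from_intervals([(0, 79), (0, 80), (100, 265)])
        trimmed, n_short = trim_fragments(frags)
        assert n_short == 1
        assert trimmed["dyad"].tolist() == [40, 182]
        assert ((trimmed["end"] - trimmed["start"]) == 80).all()


class TestCoverage:
    def test_single_fragment(self):
        track = build_coverage(frame_from_intervals([(10, 20)]), Region("chr1", 0, 30))
        expected = np.zeros(30, dtype=int)
        expected[10:20] = 1
        np.testing.assert_array_equal(track.values, expected)

    def test_linearity_of_duplicates(self):
        one = build_coverage(frame_from_intervals([(5, 15)]), Region("chr1", 0, 20))
        two = build_coverage(frame_from_intervals([(5, 15)] * 2), Region("chr1", 0, 20))
        np.testing.assert_array_equal(two.values, 2 * one.values)

    def test_matches_per_base_membership_oracle(self):
        rng = np.random.default_rng(77)
        starts = rng.integers(0, 280, 50)
        ends = starts + rng.integers(1, 60, 50)
        region = Region("chr1", 0, 300)
        frags = frame_from_intervals(list(zip(starts, np.minimum(ends, 300))))
        track = build_coverage(frags, region)
        oracle = np.array([
            sum(1 for s, e in zip(frags["start"], frags["end"]) if s <= i < e)
            for i in range(300)
        ])
        np.testing.assert_array_equal(track.values, oracle)

    def test_coverage_conservation(self):
        rng = np.random.default_rng(78)
        starts = rng.integers(0, 500, 40)
        frags = frame_from_intervals(list(zip(starts, starts + rng.integers(1, 100, 40))))
        region = Region("chr1", 100, 400)
        track = build_coverage(frags, region)
        clipped = (np.minimum(frags["end"], 400) - np.maximum(frags["start"], 100)).clip(lower=0)
        assert track.values.sum() == clipped.sum()

    def test_other_chromosome_ignored(self):
        frags = frame_from_intervals([(0, 10)], chrom="chr2")
        track = build_coverage(frags, Region("chr1", 0, 20))
        assert track.values.sum() == 0


class TestLengthHistogram:
    def test_major_minor_means(self):
        frags = frame_from_intervals([(0, 165), (0, 165), (0, 308)])
        summary = length_histogram(frags)
        assert summary.major_mean == 165
        assert summary.minor_mean == 308
        assert (summary.n_major, summary.n_minor) == (2, 1)

    def test_boundary_250_belongs_to_di(self):
        frags = frame_from_intervals([(0, 249), (0, 250), (0, 350), (0, 351)])
        summary = length_histogram(frags)
        assert summary.n_major == 1
        assert summary.n_minor == 2  # 250 and 350 inclusive; 351 neither
        mono, di = mono_di_split(frags)
        assert mono["length"].tolist() == [249]
        assert di["length"].tolist() == [250, 350]

    def test_degenerate_all_long(self):
        summary = length_histogram(frame_from_intervals([(0, 400), (0, 500)]))
        assert not summary.major_defined and not summary.minor_defined
        assert np.isnan(summary.major_mean) and np.isnan(summary.minor_mean)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no fragments"):
            length_histogram(frame_from_intervals([]))


class TestRoundTrips:
    def test_bed_roundtrip(self, tmp_path):
        frags = frame_from_intervals([(0, 165), (10, 318)])
        path = tmp_path / "frags.bed"
        write_fragments_bed(frags, path)
        back = read_fragments_bed(path)
        pd.testing.assert_frame_equal(back, frags.astype(back.dtypes))

    def test_bedgraph_runs(self, tmp_path):
        track = build_coverage(frame_from_intervals([(2, 6), (4, 8)]), Region("chr1", 0, 10))
        path = tmp_path / "cov.bedgraph"
        write_bedgraph(track, path)
        rows = pd.read_csv(path, sep="\t", header=None).values.tolist()
        assert rows == [["chr1", 0, 2, 0], ["chr1", 2, 4, 1], ["chr1", 4, 6, 2],
                        ["chr1", 6, 8, 1], ["chr1", 8, 10, 0]]
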