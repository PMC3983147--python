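"""Read filtering, 3'-end counting, the replicate filter and clustering."""

import math

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyanno.peaks import (
    ConfigurationError,
    PolyAPeakCluster,
    ReadFilterParams,
    RetainedPosition,
    ThreePrimeEndTrack,
    cluster_peaks,
    count_three_prime_ends,
    filter_reads,
    replicate_position_filter,
)

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chrT\tLN:2000\n"


def _sam_line(name, flag, pos, cigar, seq_len, mapq=60, tags=""):
    seq = "A" * seq_len
    qual = "I" * seq_len
    return (
        f"{name}\t{flag}\tchrT\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}{tags}\n"
    )


def _make_sam(tmp_path, lines):
    path = tmp_path / "reads.sam"
    path.write_text(SAM_HEADER + "".join(lines))
    return path


class TestFilterReads:
    @pytest.mark.parametrize(
        "cigar,flag,mapq,tags,kept,reason",
        [
            ("10M1I10M1D5M1I5M", 0, 60, "", True, "3 indel events pass"),
            ("5M1I5M1D5M1I5M1D10M", 0, 60, "", False, "4 indel events fail"),
            ("50M", 256, 60, "", False, "secondary alignment removed"),
            ("50M", 0, 5, "", False, "low mapping quality removed"),
            ("50M", 0, 60, "\tNH:i:3", False, "multi-mapper removed"),
            ("50M", 0, 60, "\tNH:i:1", True, "unique mapper kept"),
        ],
    )
    def test_uniqueness_and_indel_rules(self, tmp_path, cigar, flag, mapq, tags, kept, reason):
        n = sum(
            int(x)
            for x, op in _cigar_items(cigar)
            if op in "MIS"
        )
        sam = _make_sam(
            tmp_path, [_sam_line("r1", flag, 100, cigar, n, mapq=mapq, tags=tags)]
        )
        with pysam.AlignmentFile(str(sam)) as af:
            stream, stats = filter_reads(af, ReadFilterParams())
            retained = list(stream)
        assert (len(retained) == 1) == kept, reason

    def test_short_reads_removed_at_length_boundary(self, tmp_path):
        sam = _make_sam(
            tmp_path,
            [
                _sam_line("ok", 0, 100, "25M", 25),
                _sam_line("short", 0, 200, "24M", 24),
            ],
        )
        with pysam.AlignmentFile(str(sam)) as af:
            stream, stats = filter_reads(af, ReadFilterParams())
            names = [r.query_name for r in stream]
        assert names == ["ok"]
        assert stats.removed_short == 1


def _cigar_items(cigar):
    import re

    return [(m.group(1), m.group(2)) for m in re.finditer(r"(\d+)([A-Z])", cigar)]


class TestCountThreePrimeEnds:
    def test_forward_read_counts_highest_coordinate(self, tmp_path):
        sam = _make_sam(tmp_path, [_sam_line("r", 0, 100, "31M", 31)])
        with pysam.AlignmentFile(str(sam)) as af:
            track = count_three_prime_ends(af, "rep1")
        assert track.get("chrT", "+", 130) == 1

    def test_reverse_read_counts_lowest_coordinate(self, tmp_path):
        sam = _make_sam(tmp_path, [_sam_line("r", 16, 100, "31M", 31)])
        with pysam.AlignmentFile(str(sam)) as af:
            track = count_three_prime_ends(af, "rep1")
        assert track.get("chrT", "-", 100) == 1

    def test_counts_are_additive_and_conserved(self, tmp_path):
        sam = _make_sam(
            tmp_path,
            [
                _sam_line("a", 0, 100, "31M", 31),
                _sam_line("b", 0, 105, "26M", 26),
                _sam_line("c", 0, 50, "30M", 30),
            ],
        )
        with pysam.AlignmentFile(str(sam)) as af:
            track = count_three_prime_ends(af, "rep1")
        assert track.get("chrT", "+", 130) == 2
        assert track.total() == 3


def _tracks(*count_maps):
    tracks = []
    for i, cm in enumerate(count_maps, 1):
        t = ThreePrimeEndTrack(replicate_id=f"rep{i}")
        for pos, n in cm.items():
            t.add("chr1", "+", pos, n)
        tracks.append(t)
    return tracks


class TestReplicateFilter:
    def test_minimum_evidence_position_retained_with_snr_3(self):
        retained = replicate_position_filter(
            _tracks({100: 3}, {100: 3}, {100: 3}), ReadFilterParams()
        )
        assert len(retained) == 1
        assert retained[0].total == 9
        assert retained[0].snr == pytest.approx(3.0)

    @pytest.mark.parametrize("counts", [(3, 3, 2), (9, 0, 0), (2, 2, 2)])
    def test_positions_failing_any_replicate_removed(self, counts):
        maps = [{100: c} if c else {} for c in counts]
        assert replicate_position_filter(_tracks(*maps), ReadFilterParams()) == []

    def test_singleton_mode_drops_only_count_one_positions(self):
        params = ReadFilterParams(singleton_mode=True)
        retained = replicate_position_filter(_tracks({100: 1, 200: 2}), params)
        assert [r.pos for r in retained] == [200]

    def test_zero_replicates_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            replicate_position_filter([], ReadFilterParams())

    def test_monotone_in_threshold_over_random_triples(self):
        rng = np.random.default_rng(42)
        triples = rng.integers(0, 12, size=(1000, 3))
        for t in triples:
            maps = [{100: int(c)} if c else {} for c in t]
            tracks = _tracks(*maps)
            kept = [
                bool(
                    replicate_position_filter(
                        tracks, ReadFilterParams(min_reads_per_replicate=m)
                    )
                )
                for m in range(0, 8)
            ]
            # once a position falls out at threshold m it stays out above m
            assert all(a or not b for a, b in zip(kept, kept[1:])), t


def _retained(positions, counts=None):
    counts = counts or {p: 9 for p in positions}
    return [
        RetainedPosition("chr1", "+", p, (counts[p],), counts[p], math.sqrt(counts[p]))
        for p in sorted(positions)
    ]


def _brute_force_components(positions, gap):
    """Oracle: connected components of the |pi - pj| <= gap graph."""
    comps = []
    for p in sorted(positions):
        placed = False
        for comp in comps:
            if any(abs(p - q) <= gap for q in comp):
                comp.append(p)
                placed = True
                break
        if not placed:
            comps.append([p])
    # merge transitively (single linkage)
    merged = True
    while merged:
        merged = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(
                    abs(a - b) <= gap for a in comps[i] for b in comps[j]
                ):
                    comps[i].extend(comps.pop(j))
                    merged = True
                    break
            if merged:
                break
    return sorted(sorted(c) for c in comps)


class TestClusterPeaks:
    def test_three_positions_within_30bp_form_one_cluster(self):
        clusters = cluster_peaks(_retained([100, 112, 125]), max_cluster_gap=30)
        assert len(clusters) == 1
        assert clusters[0].subpeak_count == 3  # separated member positions

    def test_subpeaks_counted_as_local_maxima(self):
        counts = {100: 9, 101: 15, 102: 9, 110: 20, 111: 9, 120: 12}
        clusters = cluster_peaks(_retained(list(counts), counts), max_cluster_gap=30)
        assert len(clusters) == 1
        assert clusters[0].subpeak_count == 3

    def test_distant_positions_split(self):
        clusters = cluster_peaks(_retained([100, 200]), max_cluster_gap=25)
        assert len(clusters) == 2

    def test_singleton_cluster_has_zero_span(self):
        (c,) = cluster_peaks(_retained([500]), max_cluster_gap=25)
        assert c.span == 0
        assert c.mode_position == 500

    def test_mode_tie_breaks_most_three_prime(self):
        counts = {100: 9, 105: 9}
        (c,) = cluster_peaks(_retained([100, 105], counts), max_cluster_gap=25)
        assert c.mode_position == 105  # '+' strand: larger coordinate
        minus = [
            RetainedPosition("chr1", "-", p, (9,), 9, 3.0) for p in (100, 105)
        ]
        (c2,) = cluster_peaks(minus, max_cluster_gap=25)
        assert c2.mode_position == 100

    def test_total_count_conserved(self):
        rng = np.random.default_rng(7)
        positions = sorted(set(rng.integers(1, 2000, size=40).tolist()))
        counts = {p: int(rng.integers(9, 50)) for p in positions}
        clusters = cluster_peaks(_retained(positions, counts), max_cluster_gap=20)
        assert sum(c.total_count for c in clusters) == sum(counts.values())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        positions=st.sets(st.integers(min_value=1, max_value=500), max_size=50),
        gap=st.integers(min_value=1, max_value=60),
    )
    def test_matches_brute_force_single_linkage(self, positions, gap):
        clusters = cluster_peaks(_retained(sorted(positions)), max_cluster_gap=gap)
        got = sorted(sorted(c.member_positions) for c in clusters)
        assert got == _brute_force_components(positions, gap)
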