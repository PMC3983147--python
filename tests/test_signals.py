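"""Poly(A)-signal scanning, internal-priming, stop codons, AT fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyanno.signals import (
    assess_internal_priming,
    at_fraction,
    reverse_complement,
    scan_pas_motif,
    stop_codon_profile,
)

BASES = "ACGT"


def _genome(seq, name="chr1"):
    return {name: seq}


def _seq_with_motif(motif, distance, cleavage, length=400, fill="C"):
    """Forward-strand sequence with `motif` ending `distance` bp upstream
    of `cleavage` (1-based), everything else a motif-free fill base."""
    seq = [fill] * length
    end = cleavage - distance  # 1-based position of motif's last base
    start = end - len(motif) + 1
    seq[start - 1 : end] = list(motif)
    return "".join(seq)


def _oracle_scan(seq, cleavage, strand, window=(10, 40)):
    """Independent exhaustive Hamming<=1 hexamer scan (transcript sense)."""
    if strand == "-":
        sense = reverse_complement(seq)
        cleavage = len(seq) - cleavage + 1
    else:
        sense = seq
    hits = []
    for d in range(window[0], window[1] + 1):
        end = cleavage - d  # 1-based index of hexamer last base in sense
        start = end - 5
        if start < 1:
            continue
        hexamer = sense[start - 1 : end]
        if len(hexamer) < 6 or "N" in hexamer:
            continue
        mm = sum(a != b for a, b in zip(hexamer, "AATAAA"))
        if mm <= 1 or hexamer in ("ATTAAA", "AATAAG"):
            hits.append((min(mm, 1) if hexamer in ("ATTAAA", "AATAAG") else mm, d, hexamer))
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], abs(h[1] - 19), h[1]))
    return hits[0]


class TestScanPasMotif:
    def test_canonical_motif_at_19bp(self):
        seq = _seq_with_motif("AATAAA", 19, 300)
        hit = scan_pas_motif(_genome(seq), "chr1", 300, "+")
        assert hit.motif_class == "canonical"
        assert hit.distance_upstream == 19
        assert hit.mismatches == 0

    def test_named_variant_attaaa_at_17bp(self):
        seq = _seq_with_motif("ATTAAA", 17, 300)
        hit = scan_pas_motif(_genome(seq), "chr1", 300, "+")
        assert hit.motif_class == "variant_ATTAAA"
        assert hit.distance_upstream == 17

    def test_aataag_variant_reported(self):
        seq = _seq_with_motif("AATAAG", 20, 300)
        hit = scan_pas_motif(_genome(seq), "chr1", 300, "+")
        assert hit.motif_class == "variant_AATAAG"

    def test_tandem_motif_at_26bp(self):
        seq = _seq_with_motif("AATAAATAAA", 26, 300)
        hit = scan_pas_motif(_genome(seq), "chr1", 300, "+")
        assert hit.motif_class == "tandem"
        assert hit.distance_upstream == 26

    def test_motif_free_window_returns_none(self):
        seq = "CG" * 200
        hit = scan_pas_motif(_genome(seq), "chr1", 300, "+")
        assert hit.motif_class == "none"
        assert not hit.found

    def test_no_hit_overlapping_n_runs(self):
        seq = _seq_with_motif("AATAAA", 19, 300)
        seq = seq[:277] + "N" + seq[278:]  # N inside the planted hexamer
        hit = scan_pas_motif(_genome(seq), "chr1", 300, "+")
        assert hit.motif_class == "none"

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list(BASES), size=1000))
            cleavage = int(rng.integers(60, 940))
            hit = scan_pas_motif(_genome(seq), "chr1", cleavage, "+")
            oracle = _oracle_scan(seq, cleavage, "+")
            if oracle is None:
                assert not hit.found
            else:
                assert hit.found
                assert (hit.mismatches, hit.distance_upstream) == oracle[:2]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_minus_strand_equals_reverse_complement_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(BASES), size=600))
        cleavage = int(rng.integers(60, 540))
        minus_hit = scan_pas_motif(_genome(seq), "chr1", cleavage, "-")
        mirrored = scan_pas_motif(
            _genome(reverse_complement(seq)), "chr1", len(seq) - cleavage + 1, "+"
        )
        assert (minus_hit.motif_class, minus_hit.distance_upstream) == (
            mirrored.motif_class,
            mirrored.distance_upstream,
        )


class TestInternalPriming:
    def test_long_a_run_flagged(self):
        seq = "C" * 300 + "A" * 10 + "C" * 90
        a = assess_internal_priming(_genome(seq), "chr1", 300, "+")
        assert a.flagged
        assert a.max_a_run == 10

    def test_no_a_run_not_flagged(self):
        seq = "C" * 300 + "ACGTACGTAC" * 10
        a = assess_internal_priming(_genome(seq), "chr1", 300, "+")
        assert not a.flagged

    def test_run_one_below_threshold_not_flagged(self):
        seq = "C" * 300 + "A" * 5 + "C" * 95
        a = assess_internal_priming(_genome(seq), "chr1", 300, "+", min_a_run=6)
        assert not a.flagged
        assert a.max_a_run == 5

    def test_a_fraction_trigger(self):
        seq = "C" * 300 + "AACAACAACA" + "C" * 90  # 7/10 A, no run of 6
        a = assess_internal_priming(_genome(seq), "chr1", 300, "+")
        assert a.a_fraction_in_window == pytest.approx(0.7)
        assert a.flagged

    def test_minus_strand_reads_transcript_sense(self):
        # downstream of a minus-strand site lies at lower coordinates,
        # and genomic T reads as A in transcript sense
        seq = "C" * 100 + "T" * 10 + "C" * 100
        a = assess_internal_priming(_genome(seq), "chr1", 111, "-")
        assert a.flagged
        assert a.max_a_run == 10


class TestStopCodons:
    def test_hand_enumerated_frame0(self):
        prof = stop_codon_profile("TAATAGTGA", "+")
        assert prof.per_frame[0] == 3

    def test_poly_c_has_no_stops(self):
        prof = stop_codon_profile("C" * 30, "+")
        assert prof.per_frame == (0, 0, 0)
        assert not prof.stops_in_every_frame

    def test_strands_computed_independently_against_six_frame_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list(BASES), size=120))
            for strand in "+-":
                s = seq if strand == "+" else reverse_complement(seq)
                expected = tuple(
                    sum(
                        s[i : i + 3] in ("TAA", "TAG", "TGA")
                        for i in range(f, len(s) - 2, 3)
                    )
                    for f in range(3)
                )
                assert stop_codon_profile(seq, strand).per_frame == expected

    def test_short_interval_rejected(self):
        with pytest.raises(ValueError):
            stop_codon_profile("AT", "+")


class TestAtFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATATAT", 1.0), ("GCGCGC", 0.0), ("AATTGGCC", 0.5)],
    )
    def test_direct_counts(self, seq, expected):
        assert at_fraction(seq).fraction == pytest.approx(expected)

    def test_n_excluded_from_both_sides(self):
        r = at_fraction("AANNGG")
        assert r.fraction == pytest.approx(0.5)

    def test_all_n_flagged_undefined(self):
        r = at_fraction("NNNN")
        assert r.fraction is None
        assert r.flagged_all_n
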