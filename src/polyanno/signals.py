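"""Genomic-sequence checks around candidate cleavage sites.

Poly(A)-signal (PAS) hexamer scanning, internal-priming A-run assessment,
per-frame stop-codon profiles and AT-fraction.  All scans are performed in
transcription-strand sense: for a minus-strand site the relevant window is
reverse-complemented before scanning, so "upstream" and "downstream"
always refer to the transcript, not the reference.

Genome access works with any mapping of chromosome name to string
(including :class:`pyfaidx.Fasta`, whose records coerce to ``str``).
"""

from __future__ import annotations

from dataclasses import dataclass

CANONICAL_PAS = "AATAAA"
NAMED_VARIANTS = ("ATTAAA", "AATAAG")
TANDEM_PAS = "AATAAATAAA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive sequence fetch, clipped to contig bounds."""
    record = genome[chrom]
    seq = str(record[:])
    start = max(start, 1)
    end = min(end, len(seq))
    if start > end:
        return ""
    return seq[start - 1 : end].upper()


def contig_length(genome, chrom: str) -> int:
    return len(str(genome[chrom][:]))


@dataclass(frozen=True)
class PasMotifHit:
    """Best poly(A)-signal motif found upstream of a cleavage position."""

    motif_class: str  # canonical | one_mismatch | variant_ATTAAA | variant_AATAAG | tandem | none
    matched_sequence: str
    distance_upstream: int  # motif 3'-most base -> cleavage position, bp
    mismatches: int

    @property
    def found(self) -> bool:
        return self.motif_class != "none"


NO_HIT = PasMotifHit("none", "", -1, 2)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _transcript_sense_upstream(
    genome, chrom: str, cleavage_position: int, strand: str, span: int
) -> str:
    """Sequence of `span` bases ending at (and excluding) the cleavage base,
    transcript sense, 5'->3'; may be shorter at a contig edge."""
    if strand == "-":
        seq = fetch(genome, chrom, cleavage_position + 1, cleavage_position + span)
        return reverse_complement(seq)
    return fetch(genome, chrom, cleavage_position - span, cleavage_position - 1)


def scan_pas_motif(
    genome,
    chrom: str,
    cleavage_position: int,
    strand: str,
    window: tuple[int, int] = (10, 40),
) -> PasMotifHit:
    """Scan for the best PAS hexamer upstream of a cleavage position.

    Hexamers are scored by mismatches to the canonical AATAAA (at most 1);
    exact named variants (ATTAAA, AATAAG) are reported with their identity,
    and the tandem AATAAATAAA is reported as its own class when present.
    Ties on mismatch count are broken by distance closest to 19 bp, the
    modal observed offset.  Windows touching an N never produce a hit.

    ``distance_upstream`` is measured from the motif's 3'-most base to the
    cleavage position in transcription sense: a hexamer whose last base is
    the base immediately before the cleavage base has distance 1.
    """
    min_up, max_up = window
    span = max_up + len(CANONICAL_PAS) - 1
    seq = _transcript_sense_upstream(genome, chrom, cleavage_position, strand, span)
    # seq is transcript-sense; its last base lies 1 bp upstream of the
    # cleavage base, so a base at index i is (n - i) bp upstream.  Contig
    # clipping removes far-upstream bases only, leaving distances exact.
    best: tuple[tuple[int, int, int], PasMotifHit] | None = None
    n = len(seq)
    for start_idx in range(0, n - 5):
        hexamer = seq[start_idx : start_idx + 6]
        dist = n - (start_idx + 5)  # hexamer 3'-most base -> cleavage
        if not (min_up <= dist <= max_up):
            continue
        if "N" in hexamer:
            continue
        mm = _hamming(hexamer, CANONICAL_PAS)
        candidate: PasMotifHit | None = None
        if mm == 0:
            ten = seq[start_idx - 4 : start_idx + 6] if start_idx >= 4 else ""
            if ten == TANDEM_PAS:
                candidate = PasMotifHit("tandem", TANDEM_PAS, dist, 0)
            else:
                candidate = PasMotifHit("canonical", hexamer, dist, 0)
        elif hexamer in NAMED_VARIANTS:
            candidate = PasMotifHit(f"variant_{hexamer}", hexamer, dist, 1)
        elif mm == 1:
            candidate = PasMotifHit("one_mismatch", hexamer, dist, 1)
        if candidate is None:
            continue
        key = (candidate.mismatches, abs(dist - 19), dist)
        if best is None or key < best[0]:
            best = (key, candidate)
    return best[1] if best else NO_HIT


@dataclass(frozen=True)
class PrimingAssessment:
    """Internal-priming (genomic A-tract) assessment downstream of a site."""

    flagged: bool
    max_a_run: int
    a_fraction_in_window: float


def assess_internal_priming(
    genome,
    chrom: str,
    cleavage_position: int,
    strand: str,
    window_down: int = 10,
    min_a_run: int = 6,
    a_fraction_threshold: float = 0.7,
) -> PrimingAssessment:
    """Flag sites with adenosine runs immediately downstream.

    A site is flagged when a run of at least ``min_a_run`` consecutive A
    (transcription-strand sense) *starts* within ``window_down`` bases
    downstream of the cleavage position, or when the A fraction within
    that window reaches ``a_fraction_threshold``.
    """
    lookahead = window_down + max(min_a_run, 20)
    if strand == "-":
        raw = fetch(genome, chrom, cleavage_position - lookahead, cleavage_position - 1)
        seq = reverse_complement(raw)
    else:
        seq = fetch(genome, chrom, cleavage_position + 1, cleavage_position + lookahead)

    max_run = 0
    i = 0
    while i < min(window_down, len(seq)):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            max_run = max(max_run, j - i)
            i = j
        else:
            i += 1
    window_seq = seq[:window_down]
    a_frac = window_seq.count("A") / len(window_seq) if window_seq else 0.0
    flagged = max_run >= min_a_run or (
        bool(window_seq) and a_frac >= a_fraction_threshold
    )
    return PrimingAssessment(flagged, max_run, a_frac)


STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class StopCodonProfile:
    per_frame: tuple[int, int, int]

    @property
    def min_across_frames(self) -> int:
        return min(self.per_frame)

    @property
    def stops_in_every_frame(self) -> bool:
        return self.min_across_frames > 0


def stop_codon_profile(seq: str, strand: str = "+") -> StopCodonProfile:
    """Count TAA/TAG/TGA per reading frame on the given strand of ``seq``.

    ``seq`` is the forward-reference sequence; for strand '-' the reverse
    complement is scanned, so the two strands are computed independently.
    """
    if len(seq) < 3:
        raise ValueError("interval must be at least 3 bp for a codon scan")
    s = seq.upper() if strand == "+" else reverse_complement(seq.upper())
    counts = []
    for frame in range(3):
        n = sum(
            1
            for i in range(frame, len(s) - 2, 3)
            if s[i : i + 3] in STOP_CODONS
        )
        counts.append(n)
    return StopCodonProfile(tuple(counts))


@dataclass(frozen=True)
class AtFraction:
    fraction: float | None  # None when the interval is all-N
    flagged_all_n: bool


def at_fraction(seq: str) -> AtFraction:
    """(#A + #T) / (length excluding N); all-N intervals are flagged."""
    s = seq.upper()
    informative = sum(1 for c in s if c != "N")
    if informative == 0:
        return AtFraction(None, True)
    at = s.count("A") + s.count("T")
    return AtFraction(at / informative, False)
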