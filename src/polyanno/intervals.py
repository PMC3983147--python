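"""Stranded 1-based genomic intervals and the table length convention.

Coordinates throughout the package are 1-based and inclusive, matching how
annotation comparison tables are printed.  Minus-strand rows are sometimes
printed high-to-low; they are normalized on ingest (``start <= end``) with
the original display orientation retained so reports can reproduce the
printed order.

The *table length* of a segment is ``end - start`` — the convention that
reproduces every verified "Coverage (bp)" value in the comparison tables —
and is distinct from the inclusive base count ``end - start + 1``.
Conversion to and from 0-based half-open (BED) coordinates is centralized
here so no other module does its own off-by-one arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."

_VALID_STRANDS = {FORWARD, REVERSE, UNSTRANDED}


class InvalidIntervalError(ValueError):
    """Raised for intervals that cannot be normalized to start <= end >= 1."""


@dataclass(frozen=True)
class GenomeInterval:
    """A 1-based, inclusive, optionally stranded genomic interval.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    start, end : int
        1-based inclusive bounds with ``start <= end`` after normalization.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    display_reversed : bool
        True when the interval was supplied high-to-low (minus-strand table
        convention); preserved so writers can reproduce the original order.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    display_reversed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise InvalidIntervalError(f"invalid strand {self.strand!r}")
        if self.start > self.end:
            lo, hi = self.end, self.start
            object.__setattr__(self, "start", lo)
            object.__setattr__(self, "end", hi)
            object.__setattr__(self, "display_reversed", True)
        if self.start < 1:
            raise InvalidIntervalError(
                f"interval start must be >= 1, got {self.start}"
            )

    @classmethod
    def from_coords(
        cls, chrom: str, a: int, b: int, strand: str = UNSTRANDED
    ) -> "GenomeInterval":
        """Build an interval from possibly reversed (display-order) coordinates."""
        if a <= b:
            return cls(chrom, a, b, strand)
        return cls(chrom, b, a, strand, display_reversed=True)

    @property
    def table_length(self) -> int:
        """``end - start``: the printed "Coverage (bp)" convention."""
        return self.end - self.start

    @property
    def n_bases(self) -> int:
        """Inclusive base count, ``end - start + 1``."""
        return self.end - self.start + 1

    @property
    def display_coords(self) -> tuple[int, int]:
        """Coordinates in the orientation they were supplied in."""
        if self.display_reversed:
            return self.end, self.start
        return self.start, self.end

    def normalized(self) -> "GenomeInterval":
        """Return self (normalization happens on construction); idempotent."""
        return self

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )

    def shifted(self, offset: int) -> "GenomeInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def table_length(interval: GenomeInterval) -> int:
    """Length of a table segment: ``end - start``.

    This is the convention used by every verified per-segment coverage value
    in the annotation comparison tables (e.g. a segment printed as
    3,546,262..3,585,602 has coverage 39,340).
    """
    length = interval.end - interval.start
    if length < 0:  # unreachable after normalization; guards raw construction
        raise InvalidIntervalError("negative length after normalization")
    return length


def to_bed_coords(interval: GenomeInterval) -> tuple[str, int, int]:
    """1-based inclusive -> 0-based half-open (BED) coordinates."""
    return interval.chrom, interval.start - 1, interval.end


def from_bed_coords(
    chrom: str, bed_start: int, bed_end: int, strand: str = UNSTRANDED
) -> GenomeInterval:
    """0-based half-open (BED) -> 1-based inclusive interval."""
    if bed_end <= bed_start:
        raise InvalidIntervalError(
            f"empty or inverted BED interval [{bed_start}, {bed_end})"
        )
    return GenomeInterval(chrom, bed_start + 1, bed_end, strand)
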