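"""Gene models and re-annotation records.

A :class:`GeneModel` is an ordered list of role-typed segments (5' UTR,
body, 3' UTR, exon, intron) on one chromosome and strand.  A
:class:`ReannotationRecord` packages one or more proposed alternative
models for a gene — one per supported poly(A) site — together with the
summary interval and the segment-sum summary length used by the
comparison-table convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import GenomeInterval, table_length

SEGMENT_ROLES = ("five_prime_utr", "body", "three_prime_utr", "exon", "intron")


class StructuralError(ValueError):
    """Raised when gene-model segments violate structural invariants."""


@dataclass
class GeneModel:
    """One transcript-level gene model made of role-typed segments."""

    gene_id: str
    transcript_id: str
    source: str  # "primary-db" or "proposed"
    segments: list[tuple[str, GenomeInterval]]
    strand: str

    def __post_init__(self) -> None:
        if self.source not in ("primary-db", "proposed"):
            raise StructuralError(f"unknown source {self.source!r}")
        chroms = {iv.chrom for _, iv in self.segments}
        if len(chroms) > 1:
            raise StructuralError(f"segments span chromosomes {sorted(chroms)}")
        for role, iv in self.segments:
            if role not in SEGMENT_ROLES:
                raise StructuralError(f"unknown segment role {role!r}")
            if iv.strand not in (self.strand, "."):
                raise StructuralError(
                    f"segment strand {iv.strand} != model strand {self.strand}"
                )
        self._check_exon_intron_disjoint()

    def _check_exon_intron_disjoint(self) -> None:
        structural = sorted(
            (iv for role, iv in self.segments if role in ("exon", "intron")),
            key=lambda iv: iv.start,
        )
        for a, b in zip(structural, structural[1:]):
            if a.end >= b.start:
                raise StructuralError(
                    f"overlapping exon/intron segments {a} and {b}"
                )

    @property
    def chrom(self) -> str:
        return self.segments[0][1].chrom

    @property
    def span(self) -> GenomeInterval:
        start = min(iv.start for _, iv in self.segments)
        end = max(iv.end for _, iv in self.segments)
        return GenomeInterval(self.chrom, start, end, self.strand)

    @property
    def three_prime_end(self) -> int:
        """Transcription-direction 3'-most coordinate of the model."""
        return self.span.end if self.strand == "+" else self.span.start

    @property
    def five_prime_end(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end

    def introns(self) -> list[GenomeInterval]:
        """Explicit intron segments, or gaps between consecutive exons."""
        explicit = [iv for role, iv in self.segments if role == "intron"]
        if explicit:
            return sorted(explicit, key=lambda iv: iv.start)
        exons = sorted(
            (iv for role, iv in self.segments if role == "exon"),
            key=lambda iv: iv.start,
        )
        return [
            GenomeInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(exons, exons[1:])
            if b.start - a.end > 1
        ]


def check_abutting(
    segments: Sequence[tuple[str, GenomeInterval]], strand: str
) -> None:
    """Check that proposed segments abut in transcription order.

    Comparison tables show a +1 boundary offset between adjacent proposed
    segments in most loci but a shared boundary coordinate in others, so
    offsets of 0 and 1 are both accepted; anything else is a
    :class:`StructuralError`.
    """
    ivs = [iv for _, iv in segments]
    ordered = sorted(ivs, key=lambda iv: iv.start, reverse=(strand == "-"))
    for a, b in zip(ordered, ordered[1:]):
        if strand == "-":
            offset = a.start - b.end
        else:
            offset = b.start - a.end
        if offset not in (0, 1):
            raise StructuralError(
                f"segments do not abut (transcription-order offset {offset}): "
                f"{a} -> {b}"
            )
        if offset == 0:
            warnings.warn(
                "adjacent proposed segments share a boundary coordinate "
                f"({a} / {b}); accepted but the usual convention is a +1 offset",
                stacklevel=2,
            )


@dataclass
class ReannotationRecord:
    """Proposed re-annotation of a gene with one model per poly(A) site."""

    gene_id: str
    alternatives: list[GeneModel]
    summary_interval: GenomeInterval
    summary_length_bp: int
    span_length_bp: int
    evidence_tags: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.summary_interval.strand


def build_reannotation_record(
    gene: GeneModel,
    segments: Sequence[tuple[str, GenomeInterval]],
    evidence_tags: Iterable[frozenset[str]] | None = None,
    alternatives: Sequence[GeneModel] | None = None,
) -> ReannotationRecord:
    """Build a summary record from abutting proposed segments.

    ``summary_length_bp`` is the sum of per-segment table lengths (the
    Summary-row convention, which can differ from the span by the number of
    inter-segment boundaries); the span length is stored separately as
    ``span_length_bp``.
    """
    if not segments:
        raise StructuralError("no segments supplied")
    strands = {iv.strand for _, iv in segments} | {gene.strand}
    strands.discard(".")
    if len(strands) > 1:
        raise StructuralError(f"mixed strands in proposed segments: {strands}")
    chroms = {iv.chrom for _, iv in segments}
    if len(chroms) > 1:
        raise StructuralError(f"segments span chromosomes {sorted(chroms)}")
    check_abutting(segments, gene.strand)

    summary_length = sum(table_length(iv) for _, iv in segments)
    start = min(iv.start for _, iv in segments)
    end = max(iv.end for _, iv in segments)
    summary_interval = GenomeInterval(
        gene.chrom, start, end, gene.strand,
        display_reversed=(gene.strand == "-"),
    )
    tags = (
        {i: frozenset(t) for i, t in enumerate(evidence_tags)}
        if evidence_tags is not None
        else {}
    )
    alts = list(alternatives) if alternatives is not None else [
        GeneModel(
            gene_id=gene.gene_id,
            transcript_id=f"{gene.gene_id}.proposed.1",
            source="proposed",
            segments=list(segments),
            strand=gene.strand,
        )
    ]
    return ReannotationRecord(
        gene_id=gene.gene_id,
        alternatives=alts,
        summary_interval=summary_interval,
        summary_length_bp=summary_length,
        span_length_bp=table_length(summary_interval),
        evidence_tags=tags,
    )
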