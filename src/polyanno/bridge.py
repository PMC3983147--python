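"""Coverage bridging between annotated gene ends and downstream clusters.

RNA-seq and EST coverage are summarized as per-base depth vectors.  A
candidate downstream poly(A) cluster is *bridged* when transcription
evidence is continuous (or gap-tolerated across sources) between the
annotated 3' end and the cluster.  EST strandedness is treated as
unreliable and ignored for bridging; un-stranded RNA-seq contributes to
both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomeInterval
from .models import GeneModel
from .peaks import PolyAPeakCluster


class OrderingError(ValueError):
    """Cluster lies upstream of the annotation end it should extend."""


@dataclass
class CoverageVector:
    """Per-base read depth over a contiguous region (1-based ``start``)."""

    chrom: str
    start: int
    depth: np.ndarray
    source: str  # "RNA-seq" | "EST" | "sRNA"
    stranded: bool = False
    strand_reliability: str = "none"  # reliable | unreliable | none

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("coverage depths must be >= 0")
        if self.source == "EST":
            # archival EST strand assignment is not trusted
            self.strand_reliability = "unreliable"

    @property
    def end(self) -> int:
        return self.start + len(self.depth) - 1

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depth over [start, end] (1-based inclusive), zero-padded outside."""
        out = np.zeros(end - start + 1, dtype=float)
        lo = max(start, self.start)
        hi = min(end, self.end)
        if lo <= hi:
            out[lo - start : hi - start + 1] = self.depth[
                lo - self.start : hi - self.start + 1
            ]
        return out

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, source: str = "RNA-seq", **kw
    ) -> "CoverageVector":
        """Load a single-chromosome bedGraph into a dense vector."""
        rows = []
        chrom = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                c, s, e, v = line.split("\t")
                if chrom is None:
                    chrom = c
                elif c != chrom:
                    raise ValueError("from_bedgraph expects one chromosome")
                rows.append((int(s), int(e), float(v)))
        if not rows:
            return cls(chrom or "chr", 1, np.zeros(0), source, **kw)
        start0 = min(r[0] for r in rows)
        end0 = max(r[1] for r in rows)
        depth = np.zeros(end0 - start0, dtype=float)
        for s, e, v in rows:
            depth[s - start0 : e - start0] += v
        return cls(chrom, start0 + 1, depth, source, **kw)

    @classmethod
    def from_alignments(
        cls, alignments, chrom: str, start: int, end: int,
        source: str = "RNA-seq", **kw
    ) -> "CoverageVector":
        """Depth over [start, end] from pysam alignments (gaps excluded)."""
        depth = np.zeros(end - start + 1, dtype=float)
        for read in alignments.fetch(chrom, start - 1, end):
            for bstart, bend in read.get_blocks():  # 0-based half-open
                lo = max(bstart + 1, start)
                hi = min(bend, end)
                if lo <= hi:
                    depth[lo - start : hi - start + 1] += 1
        return cls(chrom, start, depth, source, **kw)


def junctions_from_alignments(
    alignments, chrom: str, start: int, end: int
) -> dict[tuple[int, int], int]:
    """Splice junctions (donor_end, acceptor_start), 1-based, with counts."""
    counts: dict[tuple[int, int], int] = {}
    for read in alignments.fetch(chrom, start - 1, end):
        blocks = read.get_blocks()
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 > e1:  # an N gap in the alignment
                key = (e1, s2 + 1)  # last exonic base, first exonic base
                counts[key] = counts.get(key, 0) + 1
    return counts


def junctions_from_bed(path: str | Path) -> dict[tuple[int, int], int]:
    """Junction BED6: blocks [donor_end, acceptor_start) with score = count."""
    counts: dict[tuple[int, int], int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            donor_end, acceptor_start = int(f[1]), int(f[2]) + 1
            counts[(donor_end, acceptor_start)] = counts.get(
                (donor_end, acceptor_start), 0
            ) + int(f[4])
    return counts


@dataclass(frozen=True)
class CoverageGap:
    interval: GenomeInterval
    length: int
    covered_by_other_source: bool = False


def _zero_runs(depth: np.ndarray) -> list[tuple[int, int]]:
    """Maximal zero runs as (offset, length) pairs."""
    is_zero = depth == 0
    if not is_zero.any():
        return []
    padded = np.concatenate(([False], is_zero, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def find_gaps(
    vector: CoverageVector,
    region: GenomeInterval,
    min_gap_len: int = 50,
) -> list[CoverageGap]:
    """Maximal zero-depth runs of length >= ``min_gap_len`` within region."""
    depth = vector.slice(region.start, region.end)
    gaps = []
    for offset, length in _zero_runs(depth):
        if length >= min_gap_len:
            gaps.append(
                CoverageGap(
                    GenomeInterval(
                        region.chrom,
                        region.start + offset,
                        region.start + offset + length - 1,
                        region.strand,
                    ),
                    length,
                )
            )
    return gaps


# how far past the cluster mode the terminus probe looks, so coverage
# running well beyond a candidate site is not mistaken for terminating there
_TERMINUS_LOOKAHEAD = 40


@dataclass
class BridgeParams:
    min_gap_len: int = 50
    hard_fail_gap: int = 500  # unbridged run this long -> unsupported
    min_covered_fraction: float = 0.2
    terminus_tolerance: int = 10


@dataclass
class BridgeVerdict:
    status: str  # continuous | gapped_but_bridged | unsupported
    gaps: list[CoverageGap]
    terminus_offset: int | None  # evidence end -> cluster mode, transcript sense
    covered_fraction: float


def bridge_region(
    annotation_end: int,
    cluster: PolyAPeakCluster,
    vectors: Sequence[CoverageVector],
    params: BridgeParams | None = None,
) -> BridgeVerdict:
    """Judge whether coverage bridges an annotation end to a cluster.

    * ``continuous`` — at least one source individually has no zero run of
      ``min_gap_len`` or more over the extension (the union then trivially
      has none either).
    * ``gapped_but_bridged`` — every source has significant gaps, but each
      unbridged union gap stays below ``hard_fail_gap``; gaps in one
      source that another source covers are marked as such.
    * ``unsupported`` — an unbridged union gap reaches ``hard_fail_gap``,
      or the union covers less than ``min_covered_fraction`` of the
      extension.

    ``terminus_offset`` is the transcript-sense distance from the last
    covered base to the cluster mode: positive when the evidence stops
    short, negative when it runs past the mode.
    """
    params = params or BridgeParams()
    strand = cluster.strand
    mode = cluster.mode_position
    if strand == "+":
        if mode <= annotation_end:
            raise OrderingError(
                f"cluster mode {mode} not downstream of annotation end {annotation_end}"
            )
        region = GenomeInterval(
            cluster.chrom, annotation_end + 1, mode, strand
        )
        probe = GenomeInterval(
            cluster.chrom,
            annotation_end + 1,
            mode + params.terminus_tolerance + _TERMINUS_LOOKAHEAD,
            strand,
        )
    else:
        if mode >= annotation_end:
            raise OrderingError(
                f"cluster mode {mode} not downstream of annotation end {annotation_end}"
            )
        region = GenomeInterval(
            cluster.chrom, mode, annotation_end - 1, strand
        )
        probe = GenomeInterval(
            cluster.chrom,
            max(1, mode - params.terminus_tolerance - _TERMINUS_LOOKAHEAD),
            annotation_end - 1, strand,
        )

    per_source = [v.slice(region.start, region.end) for v in vectors]
    union = (
        np.sum(per_source, axis=0)
        if per_source
        else np.zeros(region.n_bases)
    )
    covered_fraction = float((union > 0).mean()) if len(union) else 0.0

    union_vec = CoverageVector(region.chrom, region.start, union, "union")
    union_gaps = find_gaps(union_vec, region, params.min_gap_len)

    source_gapped = []
    annotated_gaps: list[CoverageGap] = []
    for v, depth in zip(vectors, per_source):
        vec = CoverageVector(region.chrom, region.start, depth, v.source)
        gaps = find_gaps(vec, region, params.min_gap_len)
        source_gapped.append(bool(gaps))
        for g in gaps:
            gap_union = union[
                g.interval.start - region.start : g.interval.end - region.start + 1
            ]
            annotated_gaps.append(
                CoverageGap(g.interval, g.length, bool((gap_union > 0).all()))
            )

    # terminus offset from the union over a probe window extended past the mode
    probe_union = np.sum(
        [v.slice(probe.start, probe.end) for v in vectors], axis=0
    ) if vectors else np.zeros(probe.n_bases)
    nz = np.flatnonzero(probe_union > 0)
    if nz.size:
        if strand == "+":
            last_covered = probe.start + int(nz[-1])
            terminus_offset = mode - last_covered
        else:
            last_covered = probe.start + int(nz[0])
            terminus_offset = last_covered - mode
    else:
        terminus_offset = None

    if (
        any(g.length >= params.hard_fail_gap for g in union_gaps)
        or covered_fraction < params.min_covered_fraction
    ):
        status = "unsupported"
    elif vectors and not all(source_gapped):
        status = "continuous"
    else:
        status = "gapped_but_bridged" if vectors else "unsupported"

    return BridgeVerdict(status, annotated_gaps, terminus_offset, covered_fraction)


@dataclass
class JunctionSupport:
    """Per-intron spanning-read support for an annotated gene model."""

    per_intron: list[tuple[GenomeInterval, int, str]]  # (intron, count, verdict)
    novel_junctions: dict[tuple[int, int], int]

    @property
    def all_supported(self) -> bool:
        return all(v == "supported" for _, _, v in self.per_intron)

    @property
    def any_unsupported(self) -> bool:
        return any(v == "unsupported" for _, _, v in self.per_intron)


def junction_concordance(
    observed: dict[tuple[int, int], int],
    gene: GeneModel,
    min_spanning_reads: int = 3,
) -> JunctionSupport:
    """Label each annotated intron supported / weak / unsupported.

    An intron [a, b] matches a junction with donor end a-1 and acceptor
    start b+1 exactly.  Observed junctions matching no annotated intron
    are reported as novel.
    """
    per_intron = []
    matched = set()
    for intron in gene.introns():
        key = (intron.start - 1, intron.end + 1)
        count = observed.get(key, 0)
        if count >= min_spanning_reads:
            verdict = "supported"
        elif count >= 1:
            verdict = "weak"
        else:
            verdict = "unsupported"
        if count:
            matched.add(key)
        per_intron.append((intron, count, verdict))
    novel = {k: v for k, v in observed.items() if k not in matched}
    return JunctionSupport(per_intron, novel)
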