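"""Strand-specific 3'-end read filtering and poly(A) peak-cluster calling.

The caller consumes per-replicate alignments (BAM/SAM via pysam) or
pre-computed per-base 3'-end count tracks (bedGraph, one file per strand
per replicate).  Reads are filtered for unique, high-quality mappings with
few indels and a minimum length; each retained read contributes one count
at its 3'-terminal aligned base (highest coordinate on the forward strand,
lowest on the reverse).  Genomic positions are retained only when every
replicate supplies at least ``min_reads_per_replicate`` reads (default 3
in each of 3 replicates, giving a Poisson signal-to-noise floor of
sqrt(9) = 3), and retained positions are grouped into clusters by
single-linkage with a maximum inter-position gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .intervals import GenomeInterval

Key = tuple[str, str]  # (chrom, strand)


class ConfigurationError(ValueError):
    pass


@dataclass
class ReadFilterParams:
    """Alignment-level and position-level retention thresholds."""

    require_unique: bool = True
    max_indels: int = 3  # "fewer than four indels"
    min_read_length: int = 25
    min_mapping_quality: int = 20
    min_reads_per_replicate: int = 3
    min_replicates: int | None = None  # None -> all replicates
    singleton_mode: bool = False  # single-replicate data: drop count-1 positions
    snr_min: float = 3.0

    def __post_init__(self) -> None:
        for name in ("max_indels", "min_read_length", "min_reads_per_replicate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class FilterStats:
    total: int = 0
    retained: int = 0
    removed_non_unique: int = 0
    removed_indels: int = 0
    removed_short: int = 0
    removed_no_cigar: int = 0


@dataclass
class ThreePrimeEndTrack:
    """Sparse per-(chrom, strand) map of position -> 3'-end read count."""

    replicate_id: str
    counts: dict[Key, dict[int, int]] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        if strand not in "+-":
            raise ConfigurationError(f"3'-end tracks are stranded; got {strand!r}")
        self.counts.setdefault((chrom, strand), {})
        self.counts[(chrom, strand)][pos] = (
            self.counts[(chrom, strand)].get(pos, 0) + n
        )

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand), {}).get(pos, 0)

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, strand: str, replicate_id: str
    ) -> "ThreePrimeEndTrack":
        """Load a per-base count track (0-based half-open bedGraph)."""
        track = cls(replicate_id=replicate_id)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split("\t")
                value = int(float(v))
                if value <= 0:
                    continue
                for pos in range(int(s) + 1, int(e) + 1):  # to 1-based
                    track.add(chrom, strand, pos, value)
        return track

    def to_bedgraph(self, path: str | Path, strand: str) -> None:
        with open(path, "w") as fh:
            for (chrom, strd), posmap in sorted(self.counts.items()):
                if strd != strand:
                    continue
                for pos in sorted(posmap):
                    fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{posmap[pos]}\n")


def _indel_events(read) -> int:
    # CIGAR ops 1 = insertion, 2 = deletion; counted as events
    return sum(1 for op, _ in (read.cigartuples or []) if op in (1, 2))


def _is_unique(read, params: ReadFilterParams) -> bool:
    if read.is_secondary or read.is_supplementary:
        return False
    if read.mapping_quality < params.min_mapping_quality:
        return False
    try:
        if read.get_tag("NH") > 1:
            return False
    except KeyError:
        pass
    return True


def filter_reads(
    alignments: Iterable, params: ReadFilterParams
) -> tuple[Iterator, FilterStats]:
    """Filter an alignment stream; returns (retained iterator, stats).

    The stats object is filled in as the iterator is consumed.
    """
    stats = FilterStats()

    def _gen():
        for read in alignments:
            if read.is_unmapped:
                continue
            stats.total += 1
            if read.cigartuples is None:
                stats.removed_no_cigar += 1
                continue
            if params.require_unique and not _is_unique(read, params):
                stats.removed_non_unique += 1
                continue
            if _indel_events(read) > params.max_indels:
                stats.removed_indels += 1
                continue
            if read.query_length and read.query_length < params.min_read_length:
                stats.removed_short += 1
                continue
            stats.retained += 1
            yield read

    return _gen(), stats


def count_three_prime_ends(
    filtered_alignments: Iterable, replicate_id: str
) -> ThreePrimeEndTrack:
    """Count the 3'-terminal aligned base of each read, strand-aware.

    Forward-strand reads contribute their highest aligned reference
    coordinate; reverse-strand reads their lowest (both 1-based).
    """
    track = ThreePrimeEndTrack(replicate_id=replicate_id)
    for read in filtered_alignments:
        chrom = read.reference_name
        if read.is_reverse:
            track.add(chrom, "-", read.reference_start + 1)
        else:
            track.add(chrom, "+", read.reference_end)  # 0-based excl == 1-based incl
    return track


@dataclass
class RetainedPosition:
    chrom: str
    strand: str
    pos: int
    per_replicate: tuple[int, ...]
    total: int
    snr: float


def replicate_position_filter(
    tracks: list[ThreePrimeEndTrack], params: ReadFilterParams
) -> list[RetainedPosition]:
    """Keep positions reproducibly covered across replicates.

    A position is retained iff its count reaches
    ``min_reads_per_replicate`` in every required replicate (all by
    default), or — in single-replicate ``singleton_mode`` — iff its count
    is at least 2.  The Poisson signal-to-noise ratio of a retained
    position is ``total / sqrt(total) = sqrt(total)``.
    """
    if not tracks:
        raise ConfigurationError("at least one replicate track is required")
    required = params.min_replicates if params.min_replicates else len(tracks)
    keys = sorted({k for t in tracks for k in t.counts})
    retained: list[RetainedPosition] = []
    for chrom, strand in keys:
        positions = sorted({p for t in tracks for p in t.counts.get((chrom, strand), {})})
        for pos in positions:
            per_rep = tuple(t.get(chrom, strand, pos) for t in tracks)
            total = sum(per_rep)
            if len(tracks) == 1 and params.singleton_mode:
                # single-replicate datasets: only singletons are dropped,
                # no Poisson S/N floor applies
                if per_rep[0] < 2:
                    continue
            else:
                ok = (
                    sum(c >= params.min_reads_per_replicate for c in per_rep)
                    >= required
                )
                if not ok:
                    continue
                if total / math.sqrt(total) < params.snr_min:
                    continue
            snr = total / math.sqrt(total)
            retained.append(
                RetainedPosition(chrom, strand, pos, per_rep, total, snr)
            )
    return retained


@dataclass
class PolyAPeakCluster:
    """A cluster of retained 3'-end positions (one candidate poly(A) site)."""

    interval: GenomeInterval
    mode_position: int
    member_positions: list[int]
    total_count: int
    per_replicate_counts: tuple[int, ...]
    snr: float
    subpeak_count: int
    motif_hit: object | None = None
    internal_priming: bool = False

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def span(self) -> int:
        return self.interval.end - self.interval.start


def _count_local_maxima(positions: list[int], heights: Mapping[int, int]) -> int:
    """Local maxima of the count profile over the cluster, plateaus once.

    Member positions separated by uncovered bases are separate sub-peaks:
    the profile drops to zero between them.
    """
    runs: list[list[int]] = []
    for p in positions:
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    count = 0
    for run in runs:
        vals = [heights[p] for p in run]
        n = len(vals)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and vals[j + 1] == vals[i]:
                j += 1
            left_ok = i == 0 or vals[i - 1] < vals[i]
            right_ok = j == n - 1 or vals[j + 1] < vals[i]
            if left_ok and right_ok:
                count += 1
            i = j + 1
    return count


def cluster_peaks(
    retained: list[RetainedPosition], max_cluster_gap: int = 25
) -> list[PolyAPeakCluster]:
    """Single-linkage clustering of retained positions per (chrom, strand).

    Consecutive positions at most ``max_cluster_gap`` apart join one
    cluster.  The cluster mode is the highest-count member position, ties
    broken toward the most 3' position in transcription direction (largest
    coordinate on '+', smallest on '-').
    """
    by_key: dict[Key, list[RetainedPosition]] = {}
    for rp in retained:
        by_key.setdefault((rp.chrom, rp.strand), []).append(rp)

    clusters: list[PolyAPeakCluster] = []
    for (chrom, strand), rps in sorted(by_key.items()):
        rps.sort(key=lambda r: r.pos)
        group: list[RetainedPosition] = []
        for rp in rps:
            if group and rp.pos - group[-1].pos > max_cluster_gap:
                clusters.append(_finalize_cluster(chrom, strand, group))
                group = []
            group.append(rp)
        if group:
            clusters.append(_finalize_cluster(chrom, strand, group))
    return clusters


def _finalize_cluster(
    chrom: str, strand: str, group: list[RetainedPosition]
) -> PolyAPeakCluster:
    positions = [r.pos for r in group]
    heights = {r.pos: r.total for r in group}
    best_count = max(heights.values())
    candidates = [p for p in positions if heights[p] == best_count]
    mode = max(candidates) if strand == "+" else min(candidates)
    n_reps = len(group[0].per_replicate)
    per_rep = tuple(
        sum(r.per_replicate[i] for r in group) for i in range(n_reps)
    )
    total = sum(heights.values())
    return PolyAPeakCluster(
        interval=GenomeInterval(chrom, positions[0], positions[-1], strand),
        mode_position=mode,
        member_positions=positions,
        total_count=total,
        per_replicate_counts=per_rep,
        snr=total / math.sqrt(total),
        subpeak_count=_count_local_maxima(positions, heights),
    )


def write_clusters_bed(clusters: list[PolyAPeakCluster], path: str | Path) -> None:
    """BED6 cluster output: score = total count, thickStart = mode."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, 1):
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.interval.start - 1),
                        str(c.interval.end),
                        f"cluster_{i}",
                        str(c.total_count),
                        c.strand,
                        str(c.mode_position - 1),
                        str(c.mode_position),
                    ]
                )
                + "\n"
            )


def write_clusters_tsv(clusters: list[PolyAPeakCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tmode\ttotal\tper_replicate\tsnr\t"
            "subpeaks\tmotif\tinternal_priming\n"
        )
        for c in clusters:
            motif = getattr(c.motif_hit, "motif_class", "none") if c.motif_hit else "none"
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.strand}\t"
                f"{c.mode_position}\t{c.total_count}\t"
                f"{','.join(map(str, c.per_replicate_counts))}\t{c.snr:.3f}\t"
                f"{c.subpeak_count}\t{motif}\t{int(c.internal_priming)}\n"
            )
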