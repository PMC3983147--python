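"""Small-RNA coverage integration: miRNA arm pairs and short features.

Mature miRNAs appear in sRNA-seq coverage as a characteristic *pair* of
short (~18-25 bp footprint) peaks — the 5p and 3p arms of the precursor
hairpin — separated by a loop-scale gap, usually with one arm (often 3p)
dominant.  A strong sRNA peak *without* this two-peak structure, but
coinciding with low-level RNA-seq expression and weak 3'-end clusters,
marks a candidate novel short feature (snoRNA-like) instead.  sRNA reads
are treated as un-stranded; strand is inherited from associated 3'-end
clusters when needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bridge import CoverageVector, _zero_runs
from .intervals import GenomeInterval
from .peaks import PolyAPeakCluster


@dataclass
class ArmPairParams:
    min_footprint: int = 18
    max_footprint: int = 25
    min_gap: int = 10
    max_gap: int = 60
    dominance_ratio: float = 1.25
    min_height: float = 1.0


@dataclass(frozen=True)
class SrnaPeak:
    interval: GenomeInterval
    height: float

    @property
    def footprint(self) -> int:
        return self.interval.n_bases


@dataclass
class ArmPair:
    """A 5p/3p mature-miRNA arm pair with a dominant-arm call."""

    locus_id: str
    five_p_peak: SrnaPeak
    three_p_peak: SrnaPeak
    dominant_arm: str  # 5p | 3p | balanced
    inter_peak_gap: int


@dataclass
class ShortFeatureCandidate:
    """A candidate un-annotated short feature (snoRNA-like)."""

    interval: GenomeInterval
    srna_peak_height: float
    drs_cluster_count: int
    rnaseq_block: Optional[GenomeInterval]
    has_two_peak_structure: bool
    external_prediction: Optional[bool] = None


def find_srna_peaks(
    coverage: CoverageVector,
    region: GenomeInterval,
    min_height: float = 1.0,
) -> list[SrnaPeak]:
    """Contiguous runs of coverage >= min_height, as peaks with max height."""
    depth = coverage.slice(region.start, region.end)
    above = depth >= min_height
    peaks = []
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        iv = GenomeInterval(
            region.chrom, region.start + int(s), region.start + int(e) - 1
        )
        peaks.append(SrnaPeak(iv, float(depth[s:e].max())))
    return peaks


def detect_arm_pairs(
    coverage: CoverageVector,
    region: GenomeInterval,
    locus_id: str = "locus",
    strand: str = "+",
    params: ArmPairParams | None = None,
) -> list[ArmPair]:
    """Pair consecutive arm-footprint peaks separated by a loop-scale gap.

    The 5p arm is the peak upstream in transcription direction (leftmost
    on '+', rightmost on '-'); dominance goes to the higher peak unless
    the height ratio stays below ``dominance_ratio`` (then balanced).
    """
    params = params or ArmPairParams()
    peaks = [
        p
        for p in find_srna_peaks(coverage, region, params.min_height)
        if params.min_footprint <= p.footprint <= params.max_footprint
    ]
    pairs = []
    i = 0
    while i + 1 < len(peaks):
        a, b = peaks[i], peaks[i + 1]
        gap = b.interval.start - a.interval.end - 1
        if params.min_gap <= gap <= params.max_gap:
            five_p, three_p = (a, b) if strand == "+" else (b, a)
            hi, lo = max(a.height, b.height), min(a.height, b.height)
            if lo == 0 or hi / lo >= params.dominance_ratio:
                dominant = "5p" if five_p.height > three_p.height else "3p"
            else:
                dominant = "balanced"
            pairs.append(
                ArmPair(
                    locus_id=f"{locus_id}_pair{len(pairs) + 1}",
                    five_p_peak=five_p,
                    three_p_peak=three_p,
                    dominant_arm=dominant,
                    inter_peak_gap=gap,
                )
            )
            i += 2
        else:
            i += 1
    return pairs


@dataclass
class PriMirna:
    """Delineated primary-miRNA transcript with excised-hairpin gaps."""

    extent: GenomeInterval
    arm_pairs: list[ArmPair]
    excision_gaps: list[GenomeInterval]
    three_prime_cluster: Optional[PolyAPeakCluster]
    tentative: bool  # True when no 3'-end cluster anchors the 3' end


def delineate_pri_mirna(
    rnaseq: CoverageVector,
    drs_clusters: Sequence[PolyAPeakCluster],
    arm_pairs: Sequence[ArmPair],
    region: GenomeInterval,
    strand: str = "+",
    max_downstream: int = 1000,
) -> Optional[PriMirna]:
    """Model the pri-miRNA as RNA-seq blocks flanking hairpin-excision gaps.

    The transcript extent runs from the first covered flanking block to
    the 3'-end cluster downstream of the 3'-most arm; with no cluster the
    extent is left open-ended at the last covered base and marked
    tentative.  Absent arm pairs, no call is made.
    """
    if not arm_pairs:
        return None
    depth = rnaseq.slice(region.start, region.end)
    nz = np.flatnonzero(depth > 0)
    if nz.size == 0:
        return None
    covered_start = region.start + int(nz[0])
    covered_end = region.start + int(nz[-1])

    arm_hi = max(
        max(p.five_p_peak.interval.end, p.three_p_peak.interval.end)
        for p in arm_pairs
    )
    arm_lo = min(
        min(p.five_p_peak.interval.start, p.three_p_peak.interval.start)
        for p in arm_pairs
    )
    three_prime_arm_edge = arm_hi if strand == "+" else arm_lo

    cluster = None
    for c in sorted(drs_clusters, key=lambda c: c.mode_position):
        if c.strand not in (strand, "."):
            continue
        if strand == "+" and (
            three_prime_arm_edge
            < c.mode_position
            <= three_prime_arm_edge + max_downstream
        ):
            cluster = c
            break
        if strand == "-" and (
            three_prime_arm_edge - max_downstream
            <= c.mode_position
            < three_prime_arm_edge
        ):
            cluster = c

    if cluster is not None:
        if strand == "+":
            extent = GenomeInterval(
                region.chrom, covered_start, cluster.mode_position, strand
            )
        else:
            extent = GenomeInterval(
                region.chrom, cluster.mode_position, covered_end, strand,
                display_reversed=True,
            )
        tentative = False
    else:
        extent = GenomeInterval(
            region.chrom, covered_start, covered_end, strand,
            display_reversed=(strand == "-"),
        )
        tentative = True

    gaps = [
        GenomeInterval(
            region.chrom,
            extent.start + off,
            extent.start + off + length - 1,
            strand,
        )
        for off, length in _zero_runs(
            rnaseq.slice(extent.start, extent.end)
        )
    ]
    return PriMirna(
        extent=extent,
        arm_pairs=list(arm_pairs),
        excision_gaps=gaps,
        three_prime_cluster=cluster,
        tentative=tentative,
    )


def call_short_feature(
    coverage: CoverageVector,
    region: GenomeInterval,
    drs_clusters: Sequence[PolyAPeakCluster],
    rnaseq_block: Optional[GenomeInterval] = None,
    external_prediction: Optional[bool] = None,
    arm_params: ArmPairParams | None = None,
    height_percentile: float = 95.0,
    min_drs_clusters: int = 2,
) -> Optional[ShortFeatureCandidate]:
    """Call a single un-paired strong sRNA peak as a short-feature candidate.

    A candidate needs a dominant sRNA peak (at or above the given height
    percentile of the region's non-zero coverage) that does *not* form an
    arm pair, plus supporting low-level RNA-seq expression and at least
    ``min_drs_clusters`` weak 3'-end clusters in the region.  Arm-paired
    peaks are routed to the miRNA logic instead, never here.
    """
    arm_params = arm_params or ArmPairParams()
    peaks = find_srna_peaks(coverage, region, arm_params.min_height)
    if not peaks:
        return None
    pairs = detect_arm_pairs(coverage, region, params=arm_params)
    paired_ivs = {
        (p.five_p_peak.interval.start, p.five_p_peak.interval.end)
        for p in pairs
    } | {
        (p.three_p_peak.interval.start, p.three_p_peak.interval.end)
        for p in pairs
    }
    unpaired = [
        p
        for p in peaks
        if (p.interval.start, p.interval.end) not in paired_ivs
    ]
    if not unpaired:
        return None
    depth = coverage.slice(region.start, region.end)
    nonzero = depth[depth > 0]
    if nonzero.size == 0:
        return None
    threshold = float(np.percentile(nonzero, height_percentile))
    strong = [p for p in unpaired if p.height >= threshold]
    if not strong:
        return None
    peak = max(strong, key=lambda p: p.height)
    in_region = [
        c
        for c in drs_clusters
        if region.start <= c.mode_position <= region.end
    ]
    if rnaseq_block is None or len(in_region) < min_drs_clusters:
        return None
    return ShortFeatureCandidate(
        interval=peak.interval,
        srna_peak_height=peak.height,
        drs_cluster_count=len(in_region),
        rnaseq_block=rnaseq_block,
        has_two_peak_structure=False,
        external_prediction=external_prediction,
    )
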