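"""Rule-based re-annotation decision tree.

A locus's assembled evidence (peak clusters on both strands, motif and
internal-priming annotations, coverage bridging, junction support, stop
profiles, stranded-data availability) is pushed through a deterministic
decision tree with eight terminal endpoints: three positive re-annotation
endpoints, three tentative endpoints and two negative (no re-annotation)
endpoints.

Node numbering follows the two worked example paths through the reference curation
flow diagram: ``1,2,3,4,5,6,7,8`` for a clean downstream 3' UTR extension
and ``1,2,3,9,10,11,12`` / ``1,2,3,9,10,13,14,15`` for an
annotated-on-the-wrong-strand locus without / with stranded RNA-seq.  The
diagram itself labels only those paths, so the remaining terminals are a
reconstruction and carry ids 16-21; the mapping is configurable data
(`NODE_LABELS`), not hard-wired prose, so predicates can be re-mapped
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bridge import BridgeVerdict, CoverageVector, JunctionSupport
from .intervals import GenomeInterval
from .models import GeneModel, ReannotationRecord, build_reannotation_record
from .peaks import PolyAPeakCluster
from .signals import PasMotifHit, PrimingAssessment, StopCodonProfile

POSITIVE_ENDPOINTS = (
    "positive_extension",
    "positive_structure_confirmed",
    "positive_novel_model",
)
TENTATIVE_ENDPOINTS = (
    "tentative_extension",
    "tentative_opposite_strand",
    "tentative_novel_feature",
)
NEGATIVE_ENDPOINTS = (
    "negative_insufficient",
    "negative_inconsistent",
)
ALL_ENDPOINTS = POSITIVE_ENDPOINTS + TENTATIVE_ENDPOINTS + NEGATIVE_ENDPOINTS

NODE_LABELS = {
    1: "load locus evidence",
    2: "existing intron/exon structure supported",
    3: "same-strand DRS clusters downstream",
    4: "RNA-seq/EST evidence extends beyond annotation (contiguously)",
    5: "evidence terminates near strongest accepted cluster",
    6: "continuous (or multi-source bridged) coverage over extension",
    7: "no contradicting sequence features at accepted sites",
    8: "terminal: positive_extension",
    9: "opposite-strand clusters within/near annotation",
    10: "stranded RNA-seq available",
    11: "opposite strand free of pervasive stop codons",
    12: "terminal: negative_inconsistent",
    13: "stranded RNA-seq confirms opposite-strand expression",
    14: "opposite-strand model can be proposed",
    15: "terminal: tentative_opposite_strand",
    16: "terminal: positive_structure_confirmed",
    17: "terminal: negative_insufficient",
    18: "terminal: tentative_novel_feature",
    19: "terminal: tentative_extension",
    20: "same-strand cluster confirms annotated 3' end",
    21: "terminal: positive_novel_model",
}

TERMINAL_ENDPOINT = {
    8: "positive_extension",
    12: "negative_inconsistent",
    15: "tentative_opposite_strand",
    16: "positive_structure_confirmed",
    17: "negative_insufficient",
    18: "tentative_novel_feature",
    19: "tentative_extension",
    21: "positive_novel_model",
}


@dataclass
class DecisionParams:
    terminus_tolerance: int = 10  # bp; "terminates near" and "confirms end"
    search_window: int = 10_000  # bp downstream cap for candidate clusters
    baseline_window: Optional[int] = None  # e.g. 300 for the automated baseline mode
    separation_min: int = 100  # bp zero-coverage separation => novel feature
    min_weak_clusters_for_novel: int = 2


@dataclass
class LocusEvidence:
    """Everything the tree needs for one gene, pre-assembled."""

    gene: GeneModel
    downstream_clusters: list[PolyAPeakCluster] = field(default_factory=list)
    near_end_clusters: list[PolyAPeakCluster] = field(default_factory=list)
    internal_clusters: list[PolyAPeakCluster] = field(default_factory=list)
    opposite_strand_clusters: list[PolyAPeakCluster] = field(default_factory=list)
    bridge_by_cluster: dict[int, BridgeVerdict] = field(default_factory=dict)
    junctions: JunctionSupport | None = None
    motif_by_cluster: dict[int, PasMotifHit] = field(default_factory=dict)
    priming_by_cluster: dict[int, PrimingAssessment] = field(default_factory=dict)
    opposite_stop_profile: StopCodonProfile | None = None
    stranded_rnaseq_available: bool = False
    stranded_rnaseq_supports_opposite: bool = False
    rnaseq_coverage: CoverageVector | None = None
    srna_single_peak: bool = False
    separation_evidence: bool | None = None  # None -> derive from coverage

    def cluster_key(self, cluster: PolyAPeakCluster) -> int:
        return id(cluster)

    def motif(self, cluster: PolyAPeakCluster) -> PasMotifHit | None:
        return self.motif_by_cluster.get(id(cluster))

    def priming(self, cluster: PolyAPeakCluster) -> PrimingAssessment | None:
        return self.priming_by_cluster.get(id(cluster))

    def bridge(self, cluster: PolyAPeakCluster) -> BridgeVerdict | None:
        return self.bridge_by_cluster.get(id(cluster))


@dataclass
class Decision:
    endpoint: str
    node_path: list[int]
    chosen_clusters: list[PolyAPeakCluster]
    proposal: ReannotationRecord | None
    rationale: dict[int, bool]
    missing_evidence: Optional[str] = None

    @property
    def endpoint_class(self) -> str:
        if self.endpoint in POSITIVE_ENDPOINTS:
            return "positive"
        if self.endpoint in TENTATIVE_ENDPOINTS:
            return "tentative"
        return "negative"


def select_supported_sites(
    clusters: Sequence[PolyAPeakCluster],
    motifs: dict[int, PasMotifHit],
    primings: dict[int, PrimingAssessment],
) -> list[PolyAPeakCluster]:
    """Accepted alternative poly(A) sites, strongest first.

    Clusters flagged as internal-priming candidates are excluded unless a
    poly(A) motif supports them (then retained, with the caller expected
    to report the conflict); survivors are ranked by total read count.
    """
    accepted = []
    for c in clusters:
        motif = motifs.get(id(c))
        priming = primings.get(id(c))
        primed = bool(priming and priming.flagged)
        motif_ok = bool(motif and motif.found)
        if primed and not motif_ok:
            continue
        accepted.append(c)
    return sorted(accepted, key=lambda c: (-c.total_count, c.mode_position))


def classify_downstream_expression(
    gene: GeneModel,
    clusters: Sequence[PolyAPeakCluster],
    rnaseq: CoverageVector | None,
    params: DecisionParams,
    srna_single_peak: bool = False,
) -> Optional[str]:
    """Distinguish a 3' UTR extension from a separate downstream feature.

    If a zero-coverage separation of at least ``separation_min`` bp lies
    between the gene end and the block of downstream expression, the
    downstream signal is a novel-feature candidate rather than part of
    the gene's 3' UTR.
    """
    if not clusters and (rnaseq is None):
        return None
    end = gene.three_prime_end
    if rnaseq is None:
        return "utr_extension"
    strand = gene.strand
    if strand == "+":
        lo, hi = end + 1, end + params.search_window
    else:
        lo, hi = max(1, end - params.search_window), end - 1
    depth = rnaseq.slice(lo, hi)
    if strand == "-":
        depth = depth[::-1]  # walk away from the gene in transcript sense
    nz = np.flatnonzero(depth > 0)
    if nz.size == 0:
        return None
    leading_zeros = int(nz[0])
    if leading_zeros >= params.separation_min:
        return "novel_feature_candidate"
    return "utr_extension"


def _build_extension_proposal(
    gene: GeneModel, accepted: Sequence[PolyAPeakCluster]
) -> ReannotationRecord:
    """Propose one alternative model per accepted site, 3' UTR ending at
    each cluster mode; the summary uses the most distal site."""
    strand = gene.strand
    end = gene.three_prime_end
    alternatives = []
    for i, cluster in enumerate(
        sorted(accepted, key=lambda c: c.mode_position, reverse=(strand == "-")),
        start=1,
    ):
        mode = cluster.mode_position
        if strand == "+":
            utr = GenomeInterval(gene.chrom, end + 1, mode, strand)
        else:
            utr = GenomeInterval(
                gene.chrom, mode, end - 1, strand, display_reversed=True
            )
        body_segments = [
            (role, iv) for role, iv in gene.segments if role != "three_prime_utr"
        ]
        old_utrs = [iv for role, iv in gene.segments if role == "three_prime_utr"]
        if old_utrs:
            # merge the old 3' UTR into the proposed one
            merged_start = min([utr.start] + [u.start for u in old_utrs])
            merged_end = max([utr.end] + [u.end for u in old_utrs])
            utr = GenomeInterval(
                gene.chrom, merged_start, merged_end, strand,
                display_reversed=(strand == "-"),
            )
        alternatives.append(
            GeneModel(
                gene_id=gene.gene_id,
                transcript_id=f"{gene.gene_id}.proposed.{i}",
                source="proposed",
                segments=body_segments + [("three_prime_utr", utr)],
                strand=strand,
            )
        )
    distal = alternatives[-1] if strand == "+" else alternatives[-1]
    distal = max(
        alternatives,
        key=lambda m: m.span.end if strand == "+" else -m.span.start,
    )
    span = gene.span
    if strand == "+":
        summary_segments = [
            ("body", GenomeInterval(gene.chrom, span.start, end, strand)),
            (
                "three_prime_utr",
                GenomeInterval(gene.chrom, end + 1, distal.span.end, strand),
            ),
        ]
    else:
        summary_segments = [
            (
                "body",
                GenomeInterval(
                    gene.chrom, end, span.end, strand, display_reversed=True
                ),
            ),
            (
                "three_prime_utr",
                GenomeInterval(
                    gene.chrom, distal.span.start, end - 1, strand,
                    display_reversed=True,
                ),
            ),
        ]
    return build_reannotation_record(
        gene, summary_segments, alternatives=alternatives
    )


def _opposite_strand_proposal(
    gene: GeneModel, clusters: Sequence[PolyAPeakCluster]
) -> ReannotationRecord | None:
    if not clusters:
        return None
    opp_strand = "-" if gene.strand == "+" else "+"
    span = gene.span
    cluster = max(clusters, key=lambda c: c.total_count)
    mode = cluster.mode_position
    if opp_strand == "-":
        start, end = min(mode, span.start), span.end
        segments = [
            ("body", GenomeInterval(gene.chrom, start, end, opp_strand,
                                    display_reversed=True))
        ]
    else:
        start, end = span.start, max(mode, span.end)
        segments = [("body", GenomeInterval(gene.chrom, start, end, opp_strand))]
    flipped = GeneModel(
        gene_id=gene.gene_id,
        transcript_id=f"{gene.gene_id}.opposite.1",
        source="proposed",
        segments=segments,
        strand=opp_strand,
    )
    return build_reannotation_record(flipped, segments, alternatives=[flipped])


def evaluate_locus(
    evidence: LocusEvidence, params: DecisionParams | None = None
) -> Decision:
    """Traverse the decision tree for one locus; fully deterministic."""
    params = params or DecisionParams()
    path: list[int] = []
    rationale: dict[int, bool] = {}

    def visit(node: int, outcome: bool | None = None) -> None:
        path.append(node)
        if outcome is not None:
            rationale[node] = outcome

    def terminal(node: int, chosen=None, proposal=None, missing=None) -> Decision:
        visit(node)
        return Decision(
            endpoint=TERMINAL_ENDPOINT[node],
            node_path=path,
            chosen_clusters=list(chosen or []),
            proposal=proposal,
            rationale=rationale,
            missing_evidence=missing,
        )

    gene = evidence.gene
    visit(1)
    if gene is None:
        return terminal(17, missing="gene model")

    structure_ok = (
        evidence.junctions is None or not evidence.junctions.any_unsupported
    )
    visit(2, structure_ok)

    # apply the (optional) automated-baseline downstream search window
    downstream = evidence.downstream_clusters
    if params.baseline_window is not None:
        end = gene.three_prime_end
        if gene.strand == "+":
            downstream = [
                c for c in downstream
                if c.mode_position <= end + params.baseline_window
            ]
        else:
            downstream = [
                c for c in downstream
                if c.mode_position >= end - params.baseline_window
            ]

    has_downstream = bool(downstream)
    visit(3, has_downstream)

    if has_downstream:
        accepted = select_supported_sites(
            downstream, evidence.motif_by_cluster, evidence.priming_by_cluster
        )
        # node 4: does broad-coverage evidence extend beyond the annotation,
        # contiguously with the gene?
        kind = classify_downstream_expression(
            gene, downstream, evidence.rnaseq_coverage, params,
            evidence.srna_single_peak,
        )
        if evidence.separation_evidence is True or kind == "novel_feature_candidate":
            visit(4, False)
            return terminal(18, chosen=downstream)
        extends = kind == "utr_extension" or any(
            evidence.bridge(c) is not None for c in downstream
        )
        visit(4, extends)
        if not extends:
            near = evidence.near_end_clusters
            visit(20, bool(near))
            if near:
                return terminal(16, chosen=near)
            return terminal(17, missing="bridging coverage")
        if not accepted:
            # every downstream cluster looks like internal priming
            near = evidence.near_end_clusters
            if near:
                visit(20, True)
                return terminal(16, chosen=near)
            return terminal(17, missing="motif-supported cluster")
        # node 5 asks whether the broad-coverage evidence terminates at an
        # accepted DRS site; the relevant anchor is the most distal
        # accepted cluster (in the worked examples the dominant, most
        # distal peak is where the RNA-seq/EST coverage ends)
        anchor = max(
            accepted,
            key=lambda c: c.mode_position if gene.strand == "+" else -c.mode_position,
        )
        verdict = evidence.bridge(anchor)
        terminates_near = bool(
            verdict is not None
            and verdict.terminus_offset is not None
            and abs(verdict.terminus_offset) <= params.terminus_tolerance
        )
        visit(5, terminates_near)
        if not terminates_near:
            return terminal(
                19,
                chosen=accepted,
                proposal=_build_extension_proposal(gene, accepted),
            )
        continuous = verdict.status == "continuous"
        bridged = verdict.status == "gapped_but_bridged"
        visit(6, continuous)
        if verdict.status == "unsupported":
            return terminal(17, missing="continuous coverage")
        if bridged:
            return terminal(
                19,
                chosen=accepted,
                proposal=_build_extension_proposal(gene, accepted),
            )
        clean = all(
            not (evidence.priming(c) and evidence.priming(c).flagged)
            or (evidence.motif(c) and evidence.motif(c).found)
            for c in accepted
        )
        visit(7, clean)
        if not clean:
            return terminal(12, chosen=accepted)
        return terminal(
            8, chosen=accepted, proposal=_build_extension_proposal(gene, accepted)
        )

    # no same-strand downstream clusters
    has_opposite = bool(evidence.opposite_strand_clusters)
    visit(9, has_opposite)
    if not has_opposite:
        near = evidence.near_end_clusters
        if near:
            visit(20, True)
            return terminal(16, chosen=near)
        internal = select_supported_sites(
            evidence.internal_clusters,
            evidence.motif_by_cluster,
            evidence.priming_by_cluster,
        )
        if internal and (
            evidence.junctions is None or not evidence.junctions.any_unsupported
        ):
            return terminal(21, chosen=internal)
        return terminal(17, missing="DRS clusters")

    stranded = evidence.stranded_rnaseq_available
    visit(10, stranded)
    if not stranded:
        stops = evidence.opposite_stop_profile
        pervasive_stops = bool(stops and stops.stops_in_every_frame)
        visit(11, not pervasive_stops)
        if pervasive_stops:
            return terminal(12, chosen=evidence.opposite_strand_clusters)
        return terminal(
            15,
            chosen=evidence.opposite_strand_clusters,
            proposal=_opposite_strand_proposal(
                gene, evidence.opposite_strand_clusters
            ),
        )
    confirms = evidence.stranded_rnaseq_supports_opposite
    visit(13, confirms)
    if not confirms:
        return terminal(12, chosen=evidence.opposite_strand_clusters)
    proposal = _opposite_strand_proposal(gene, evidence.opposite_strand_clusters)
    visit(14, proposal is not None)
    if proposal is None:
        return terminal(17, missing="opposite-strand model")
    return terminal(
        15, chosen=evidence.opposite_strand_clusters, proposal=proposal
    )
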