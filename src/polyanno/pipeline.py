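"""End-to-end orchestration: load a locus directory, assemble evidence,
run the decision tree and the small-RNA analyses.

A *scenario directory* (as written by :mod:`polyanno.simulate`, or
assembled by hand from real data exports) contains a genome FASTA, a GFF3
annotation, per-replicate stranded 3'-end bedGraph tracks, un-stranded
RNA-seq coverage, a junction BED, an EST BED12 and sRNA coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyfaidx

from . import annotio, bridge, decision, peaks, signals, srna
from .config import PipelineConfig
from .intervals import GenomeInterval
from .models import GeneModel


@dataclass
class ScenarioData:
    """Parsed inputs for one locus/scenario."""

    genome: object
    contig: str
    contig_length: int
    genes: list[GeneModel]
    drs_tracks: list[peaks.ThreePrimeEndTrack]
    rnaseq: bridge.CoverageVector
    est: bridge.CoverageVector
    srna: bridge.CoverageVector
    junctions: dict[tuple[int, int], int]
    truth: dict | None = None


def load_scenario(directory: str | Path) -> ScenarioData:
    directory = Path(directory)
    genome = pyfaidx.Fasta(str(directory / "genome.fa"))
    contig = list(genome.keys())[0]
    contig_length = len(genome[contig])

    genes = annotio.read_annotations(directory / "annotation.gff3", "GFF3")

    tracks = []
    rep = 1
    while (directory / f"drs_rep{rep}_plus.bedgraph").exists():
        track = peaks.ThreePrimeEndTrack.from_bedgraph(
            directory / f"drs_rep{rep}_plus.bedgraph", "+", f"rep{rep}"
        )
        minus = peaks.ThreePrimeEndTrack.from_bedgraph(
            directory / f"drs_rep{rep}_minus.bedgraph", "-", f"rep{rep}"
        )
        track.counts.update(minus.counts)
        tracks.append(track)
        rep += 1

    rnaseq = bridge.CoverageVector.from_bedgraph(
        directory / "rnaseq.bedgraph", source="RNA-seq"
    )
    est_models = annotio.read_annotations(directory / "est.bed12", "BED12")
    est = _est_coverage(est_models, contig, contig_length)
    srna_cov = bridge.CoverageVector.from_bedgraph(
        directory / "srna.bedgraph", source="sRNA"
    )
    junctions = bridge.junctions_from_bed(directory / "junctions.bed")

    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        import json

        truth = json.loads(truth_path.read_text())

    return ScenarioData(
        genome=genome,
        contig=contig,
        contig_length=contig_length,
        genes=genes,
        drs_tracks=tracks,
        rnaseq=rnaseq,
        est=est,
        srna=srna_cov,
        junctions=junctions,
        truth=truth,
    )


def _est_coverage(
    est_models: list[GeneModel], contig: str, contig_length: int
) -> bridge.CoverageVector:
    """Collapse EST alignments to un-stranded depth (strand untrusted)."""
    depth = np.zeros(contig_length, dtype=float)
    for m in est_models:
        for _, iv in m.segments:
            depth[iv.start - 1 : iv.end] += 1
    return bridge.CoverageVector(contig, 1, depth, source="EST")


def call_clusters(
    data: ScenarioData, config: PipelineConfig
) -> list[peaks.PolyAPeakCluster]:
    retained = peaks.replicate_position_filter(data.drs_tracks, config.read_filter)
    return peaks.cluster_peaks(retained, config.max_cluster_gap)


def _annotate_cluster_signals(
    clusters, genome, config: PipelineConfig
) -> tuple[dict, dict]:
    motifs, primings = {}, {}
    sp = config.signals
    for c in clusters:
        motifs[id(c)] = signals.scan_pas_motif(
            genome, c.chrom, c.mode_position, c.strand,
            (sp.pas_window_min, sp.pas_window_max),
        )
        primings[id(c)] = signals.assess_internal_priming(
            genome, c.chrom, c.mode_position, c.strand,
            sp.priming_window_down, sp.priming_min_a_run, sp.priming_a_fraction,
        )
        c.motif_hit = motifs[id(c)]
        c.internal_priming = primings[id(c)].flagged
    return motifs, primings


def assemble_locus_evidence(
    data: ScenarioData,
    gene: GeneModel,
    clusters: list[peaks.PolyAPeakCluster],
    config: PipelineConfig,
) -> decision.LocusEvidence:
    """Sort clusters relative to one gene and attach all evidence layers."""
    dp = config.decision
    end = gene.three_prime_end
    strand = gene.strand
    span = gene.span
    opp = "-" if strand == "+" else "+"

    near, downstream, internal, opposite = [], [], [], []
    for c in clusters:
        if c.chrom != gene.chrom:
            continue
        mode = c.mode_position
        if c.strand == strand:
            if abs(mode - end) <= dp.terminus_tolerance:
                near.append(c)
            elif strand == "+" and end < mode <= end + dp.search_window:
                downstream.append(c)
            elif strand == "-" and end - dp.search_window <= mode < end:
                downstream.append(c)
            elif span.start <= mode <= span.end:
                internal.append(c)
        elif c.strand == opp:
            margin = config.opposite_strand_margin
            if span.start - margin <= mode <= span.end + margin:
                opposite.append(c)

    motifs, primings = _annotate_cluster_signals(
        near + downstream + internal + opposite, data.genome, config
    )

    vectors = [data.rnaseq, data.est]
    bridges = {}
    for c in downstream:
        try:
            bridges[id(c)] = bridge.bridge_region(end, c, vectors, config.bridge)
        except bridge.OrderingError:
            continue

    junction_support = bridge.junction_concordance(data.junctions, gene)

    opp_seq = signals.fetch(data.genome, gene.chrom, span.start, span.end)
    opp_stops = (
        signals.stop_codon_profile(opp_seq, strand=opp)
        if len(opp_seq) >= 3
        else None
    )

    stranded = config.stranded_rnaseq_available
    return decision.LocusEvidence(
        gene=gene,
        downstream_clusters=downstream,
        near_end_clusters=near,
        internal_clusters=internal,
        opposite_strand_clusters=opposite,
        bridge_by_cluster=bridges,
        junctions=junction_support,
        motif_by_cluster=motifs,
        priming_by_cluster=primings,
        opposite_stop_profile=opp_stops,
        stranded_rnaseq_available=stranded,
        # un-stranded RNA-seq aligns over the locus; when a stranded
        # library is supplied it is taken to resolve the strand question
        stranded_rnaseq_supports_opposite=stranded and bool(opposite),
        rnaseq_coverage=data.rnaseq,
    )


@dataclass
class SrnaAnalysis:
    arm_pairs: list[srna.ArmPair] = field(default_factory=list)
    pri_mirna: srna.PriMirna | None = None
    short_features: list[srna.ShortFeatureCandidate] = field(default_factory=list)


def analyse_srna(
    data: ScenarioData,
    clusters: list[peaks.PolyAPeakCluster],
    config: PipelineConfig,
) -> SrnaAnalysis:
    region = GenomeInterval(data.contig, 1, data.contig_length)
    pairs = srna.detect_arm_pairs(
        data.srna, region, locus_id=data.contig, strand="+",
        params=config.arm_pair,
    )
    result = SrnaAnalysis(arm_pairs=pairs)
    if pairs:
        # delineate around the arm pairs so flanking genes' coverage does
        # not get absorbed into the pri-miRNA extent
        lo = min(p.five_p_peak.interval.start for p in pairs)
        hi = max(p.three_p_peak.interval.end for p in pairs)
        pad = 1_000
        locus = GenomeInterval(
            data.contig,
            max(1, lo - pad),
            min(data.contig_length, hi + pad),
        )
        result.pri_mirna = srna.delineate_pri_mirna(
            data.rnaseq, clusters, pairs, locus, strand="+"
        )
        return result

    # no arm pairs: look for an un-paired short-feature candidate in the
    # covered blocks downstream of each gene
    for gene in data.genes:
        block = _downstream_block(data, gene, config)
        if block is None:
            continue
        scan = GenomeInterval(data.contig, block.start, block.end)
        candidate = srna.call_short_feature(
            data.srna, scan, clusters, rnaseq_block=block,
            arm_params=config.arm_pair,
        )
        if candidate is not None:
            result.short_features.append(candidate)
    return result


def _downstream_block(
    data: ScenarioData, gene: GeneModel, config: PipelineConfig
) -> GenomeInterval | None:
    """First contiguous RNA-seq block downstream of the gene end."""
    end = gene.three_prime_end
    window = config.decision.search_window
    if gene.strand == "+":
        lo, hi = end + 1, min(end + window, data.contig_length)
    else:
        lo, hi = max(1, end - window), end - 1
    depth = data.rnaseq.slice(lo, hi)
    nz = np.flatnonzero(depth > 0)
    if nz.size == 0:
        return None
    first = int(nz[0])
    run_end = first
    while run_end + 1 < len(depth) and depth[run_end + 1] > 0:
        run_end += 1
    return GenomeInterval(data.contig, lo + first, lo + run_end, gene.strand)


@dataclass
class AnnotationResult:
    decisions: dict[str, decision.Decision]
    clusters: list[peaks.PolyAPeakCluster]
    srna: SrnaAnalysis


def annotate(
    data: ScenarioData, config: PipelineConfig | None = None
) -> AnnotationResult:
    """Run the full pipeline on loaded scenario data."""
    config = config or PipelineConfig()
    clusters = call_clusters(data, config)
    decisions = {}
    for gene in data.genes:
        evidence = assemble_locus_evidence(data, gene, clusters, config)
        decisions[gene.transcript_id] = decision.evaluate_locus(
            evidence, config.decision
        )
    srna_result = analyse_srna(data, clusters, config)
    return AnnotationResult(decisions=decisions, clusters=clusters, srna=srna_result)


def write_decision_log(result: AnnotationResult, path: str | Path) -> None:
    """TSV decision log: gene, endpoint, node path, per-node booleans."""
    with open(path, "w") as fh:
        fh.write("transcript\tendpoint\tendpoint_class\tnode_path\trationale\n")
        for tid in sorted(result.decisions):
            d = result.decisions[tid]
            rationale = ";".join(
                f"{k}={'T' if v else 'F'}" for k, v in sorted(d.rationale.items())
            )
            fh.write(
                f"{tid}\t{d.endpoint}\t{d.endpoint_class}\t"
                f"{','.join(map(str, d.node_path))}\t{rationale}\n"
            )


def write_proposals_gff3(result: AnnotationResult, path: str | Path) -> None:
    proposals = [
        d.proposal
        for _, d in sorted(result.decisions.items())
        if d.proposal is not None
    ]
    annotio.write_annotations(proposals, path, "GFF3")


def format_report(result: AnnotationResult) -> str:
    """Human-readable per-locus report."""
    lines = []
    for tid in sorted(result.decisions):
        d = result.decisions[tid]
        lines.append(f"== {tid} ==")
        lines.append(f"endpoint: {d.endpoint} ({d.endpoint_class})")
        lines.append(f"node path: {' -> '.join(map(str, d.node_path))}")
        for node in d.node_path:
            label = decision.NODE_LABELS.get(node, "?")
            flag = d.rationale.get(node)
            mark = {True: "yes", False: "no", None: "-"}[flag]
            lines.append(f"  [{node:>2}] {label}: {mark}")
        if d.chosen_clusters:
            modes = ", ".join(str(c.mode_position) for c in d.chosen_clusters)
            lines.append(f"clusters: {modes}")
        if d.proposal is not None:
            rec = d.proposal
            a, b = rec.summary_interval.display_coords
            lines.append(
                f"proposal: {rec.gene_id} {a}-{b} ({rec.strand}) "
                f"summary {rec.summary_length_bp} bp over "
                f"{len(rec.alternatives)} alternative model(s)"
            )
        if d.missing_evidence:
            lines.append(f"missing evidence: {d.missing_evidence}")
        lines.append("")
    if result.srna.arm_pairs:
        lines.append("== small RNA ==")
        for p in result.srna.arm_pairs:
            lines.append(
                f"arm pair {p.locus_id}: 5p {p.five_p_peak.interval.start}-"
                f"{p.five_p_peak.interval.end} (h={p.five_p_peak.height:.0f}) / "
                f"3p {p.three_p_peak.interval.start}-{p.three_p_peak.interval.end} "
                f"(h={p.three_p_peak.height:.0f}) dominant={p.dominant_arm}"
            )
        pri = result.srna.pri_mirna
        if pri is not None:
            lines.append(
                f"pri-miRNA extent {pri.extent.start}-{pri.extent.end}, "
                f"{len(pri.excision_gaps)} excision gap(s), "
                f"tentative={pri.tentative}"
            )
    for sf in result.srna.short_features:
        lines.append(
            f"short-feature candidate {sf.interval.start}-{sf.interval.end} "
            f"(sRNA height {sf.srna_peak_height:.0f}, "
            f"{sf.drs_cluster_count} DRS clusters, "
            f"two-peak structure: {sf.has_two_peak_structure})"
        )
    return "\n".join(lines) + "\n"
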