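"""Decision-tree traversal: endpoints, node paths, proposals, invariants."""

import numpy as np
import pytest

from polyanno.bridge import BridgeVerdict, CoverageVector, JunctionSupport
from polyanno.decision import (
    ALL_ENDPOINTS,
    NEGATIVE_ENDPOINTS,
    POSITIVE_ENDPOINTS,
    TENTATIVE_ENDPOINTS,
    DecisionParams,
    LocusEvidence,
    classify_downstream_expression,
    evaluate_locus,
    select_supported_sites,
)
from polyanno.intervals import GenomeInterval
from polyanno.models import GeneModel
from polyanno.peaks import PolyAPeakCluster
from polyanno.signals import PasMotifHit, PrimingAssessment, StopCodonProfile

NO_HIT = PasMotifHit("none", "", -1, 2)
CANONICAL = PasMotifHit("canonical", "AATAAA", 19, 0)
PRIMED = PrimingAssessment(True, 10, 0.9)
CLEAN = PrimingAssessment(False, 2, 0.2)


def _gene(strand="+", lo=1000, hi=2000):
    return GeneModel(
        gene_id="g",
        transcript_id="g.1",
        source="primary-db",
        segments=[("exon", GenomeInterval("chr1", lo, hi, strand))],
        strand=strand,
    )


def _cluster(mode, strand="+", total=60):
    return PolyAPeakCluster(
        interval=GenomeInterval("chr1", mode - 1, mode + 1, strand),
        mode_position=mode,
        member_positions=[mode],
        total_count=total,
        per_replicate_counts=(total // 3,) * 3,
        snr=total**0.5,
        subpeak_count=1,
    )


def _verdict(status="continuous", offset=-1):
    return BridgeVerdict(status, [], offset, 1.0)


def _coverage_to(start, end, contig_len=12_000):
    depth = np.zeros(contig_len)
    depth[start - 1 : end] = 5.0
    return CoverageVector("chr1", 1, depth, "RNA-seq")


def _extension_evidence(**overrides):
    gene = _gene()
    cluster = _cluster(3500)
    ev = LocusEvidence(
        gene=gene,
        downstream_clusters=[cluster],
        bridge_by_cluster={id(cluster): _verdict()},
        motif_by_cluster={id(cluster): CANONICAL},
        priming_by_cluster={id(cluster): CLEAN},
        rnaseq_coverage=_coverage_to(1000, 3501),
    )
    for k, v in overrides.items():
        setattr(ev, k, v)
    return ev


class TestEndpointSet:
    def test_three_three_two_endpoint_kinds(self):
        assert len(POSITIVE_ENDPOINTS) == 3
        assert len(TENTATIVE_ENDPOINTS) == 3
        assert len(NEGATIVE_ENDPOINTS) == 2
        assert len(set(ALL_ENDPOINTS)) == 8


class TestWorkedPaths:
    def test_clean_extension_follows_path_1_to_8(self):
        decision = evaluate_locus(_extension_evidence())
        assert decision.node_path == [1, 2, 3, 4, 5, 6, 7, 8]
        assert decision.endpoint == "positive_extension"
        assert decision.proposal is not None

    def test_wrong_strand_without_stranded_data(self):
        gene = _gene()
        opp = _cluster(1010, strand="-")
        ev = LocusEvidence(
            gene=gene,
            opposite_strand_clusters=[opp],
            opposite_stop_profile=StopCodonProfile((2, 3, 1)),
            stranded_rnaseq_available=False,
            rnaseq_coverage=_coverage_to(1000, 2000),
        )
        decision = evaluate_locus(ev)
        assert decision.node_path == [1, 2, 3, 9, 10, 11, 12]
        assert decision.endpoint == "negative_inconsistent"

    def test_wrong_strand_with_stranded_data(self):
        gene = _gene()
        opp = _cluster(1010, strand="-")
        ev = LocusEvidence(
            gene=gene,
            opposite_strand_clusters=[opp],
            opposite_stop_profile=StopCodonProfile((2, 3, 1)),
            stranded_rnaseq_available=True,
            stranded_rnaseq_supports_opposite=True,
            rnaseq_coverage=_coverage_to(1000, 2000),
        )
        decision = evaluate_locus(ev)
        assert decision.node_path == [1, 2, 3, 9, 10, 13, 14, 15]
        assert decision.endpoint == "tentative_opposite_strand"


class TestOtherEndpoints:
    def test_cluster_at_annotated_end_confirms_structure(self):
        gene = _gene()
        near = _cluster(2003)
        ev = LocusEvidence(
            gene=gene,
            near_end_clusters=[near],
            rnaseq_coverage=_coverage_to(1000, 2000),
        )
        decision = evaluate_locus(ev)
        assert decision.endpoint == "positive_structure_confirmed"

    def test_internal_motif_supported_cluster_proposes_novel_model(self):
        gene = _gene()
        internal = _cluster(1500)
        ev = LocusEvidence(
            gene=gene,
            internal_clusters=[internal],
            motif_by_cluster={id(internal): CANONICAL},
            priming_by_cluster={id(internal): CLEAN},
            rnaseq_coverage=_coverage_to(1000, 2000),
        )
        decision = evaluate_locus(ev)
        assert decision.endpoint == "positive_novel_model"

    def test_gapped_but_bridged_extension_is_tentative(self):
        ev = _extension_evidence()
        (cluster,) = ev.downstream_clusters
        ev.bridge_by_cluster = {id(cluster): _verdict("gapped_but_bridged", -1)}
        decision = evaluate_locus(ev)
        assert decision.endpoint == "tentative_extension"

    def test_separated_downstream_expression_is_novel_feature(self):
        gene = _gene()
        cluster = _cluster(3500)
        ev = LocusEvidence(
            gene=gene,
            downstream_clusters=[cluster],
            motif_by_cluster={id(cluster): CANONICAL},
            priming_by_cluster={id(cluster): CLEAN},
            rnaseq_coverage=_coverage_to(3000, 3600),  # separated block
        )
        decision = evaluate_locus(ev)
        assert decision.endpoint == "tentative_novel_feature"
        assert decision.node_path == [1, 2, 3, 4, 18]

    def test_no_evidence_at_all_is_insufficient(self):
        ev = LocusEvidence(gene=_gene())
        decision = evaluate_locus(ev)
        assert decision.endpoint == "negative_insufficient"
        assert decision.missing_evidence is not None


class TestDeterminismAndInvariants:
    def test_identical_evidence_identical_decision(self):
        a = evaluate_locus(_extension_evidence())
        b = evaluate_locus(_extension_evidence())
        assert a.endpoint == b.endpoint
        assert a.node_path == b.node_path
        assert a.rationale == b.rationale

    def test_proposal_places_cluster_mode_at_utr_end(self):
        decision = evaluate_locus(_extension_evidence())
        rec = decision.proposal
        for model in rec.alternatives:
            utr = [iv for role, iv in model.segments if role == "three_prime_utr"]
            assert utr, "every alternative carries a proposed 3' UTR"
            assert utr[0].end in {
                c.mode_position for c in decision.chosen_clusters
            }

    def test_adding_bridge_source_never_turns_positive_negative(self):
        ev = _extension_evidence()
        base = evaluate_locus(ev)
        assert base.endpoint_class == "positive"
        # an additional (EST) bridging verdict can only improve status
        (cluster,) = ev.downstream_clusters
        ev.bridge_by_cluster = {id(cluster): _verdict("continuous", -1)}
        again = evaluate_locus(ev)
        assert again.endpoint_class != "negative"


class TestSelectSupportedSites:
    def test_rule_table(self):
        c_motif = _cluster(3000, total=90)
        c_decoy = _cluster(3100, total=60)
        c_both = _cluster(3200, total=30)
        motifs = {
            id(c_motif): CANONICAL,
            id(c_decoy): NO_HIT,
            id(c_both): CANONICAL,
        }
        primings = {
            id(c_motif): CLEAN,
            id(c_decoy): PRIMED,
            id(c_both): PRIMED,
        }
        accepted = select_supported_sites(
            [c_motif, c_decoy, c_both], motifs, primings
        )
        assert c_decoy not in accepted  # primed, motif-less -> excluded
        assert c_both in accepted  # primed but canonical motif -> retained
        assert accepted[0] is c_motif  # ranked by total count

    def test_four_motif_supported_clusters_give_four_alternatives(self):
        clusters = [_cluster(3000 + 500 * k, total=60 + k) for k in range(4)]
        motifs = {id(c): CANONICAL for c in clusters}
        primings = {id(c): CLEAN for c in clusters}
        assert len(select_supported_sites(clusters, motifs, primings)) == 4


class TestClassifyDownstream:
    def test_contiguous_coverage_is_utr_extension(self):
        gene = _gene()
        out = classify_downstream_expression(
            gene, [_cluster(3500)], _coverage_to(1000, 3600), DecisionParams()
        )
        assert out == "utr_extension"

    def test_separated_block_is_novel_candidate(self):
        gene = _gene()
        out = classify_downstream_expression(
            gene, [_cluster(3500)], _coverage_to(2500, 3600), DecisionParams()
        )
        assert out == "novel_feature_candidate"

    def test_empty_downstream_is_neither(self):
        gene = _gene()
        out = classify_downstream_expression(
            gene, [], _coverage_to(1000, 2000), DecisionParams()
        )
        assert out is None
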