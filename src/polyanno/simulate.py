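"""Self-contained synthetic test loci with ground truth.

Each scenario emits a complete mini-study in standard formats — genome
FASTA, GFF3 annotation, three replicate strand-specific 3'-end count
tracks (bedGraph), un-stranded RNA-seq coverage (bedGraph) with splice
junctions (BED), sparse strand-unreliable ESTs (BED12), sRNA coverage
(bedGraph) — plus a JSON truth file listing every planted feature, so any
pipeline stage can be scored against what was actually put in.

Statistical structure emulated:

* 3'-end reads land at the true cleavage site plus a discrete triangular
  jitter on {-2..+2} (the stated positional accuracy of the technology);
  per-site per-replicate read counts are Poisson.
* Background 3'-end noise is Poisson per base per replicate, thin enough
  that the 3-reads-in-each-of-3-replicates filter removes essentially all
  of it.
* Poly(A)-signal hexamers (AATAAA) are planted 15-22 bp upstream of every
  true site; internal-priming decoys get a genomic A-run immediately
  downstream and a guaranteed motif-free upstream window.
* RNA-seq coverage is piecewise-constant per 50 bp window with lognormal
  multipliers, occasional sub-threshold dropout windows upstream of the
  annotated end, and explicitly planted zero gaps downstream.
* ESTs are sparse and their strand flag is flipped at a stated error rate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

SCENARIOS = (
    "simple_extension",
    "ambiguous_multi_peak",
    "curated_two_sites",
    "long_extension_past_window",
    "wrong_strand",
    "overlapping_convergent",
    "overlapping_models_broad_peak",
    "pri_mirna",
    "novel_short_feature",
)

# forward-strand plant whose reverse complement ("TAACTAACTAA") contains a
# stop codon in all three reading frames at any phase
_OPPOSITE_STOP_PLANT = "TTAGTTAGTTA"
# motif-free upstream pad for internal-priming decoys (no hexamer within
# one mismatch of AATAAA, and no ATTAAA/AATAAG)
_DECOY_UPSTREAM_PAD = "CG" * 23
_DECOY_A_RUN = "A" * 12
_SITE_DOWNSTREAM_PAD = "CGTCGTGCTC"

_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_JITTER_WEIGHTS = np.array([1, 2, 3, 2, 1]) / 9.0


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    """Geometry, counts and noise for one synthetic locus."""

    scenario: str
    seed: int = 0
    contig: str = "chrS"
    contig_length: int = 14_000
    gene_start: int = 2_001
    utr5_len: int = 200
    exon1_len: int = 800  # includes the 5' UTR
    intron_len: int = 400
    exon2_len: int = 1_000  # includes the annotated 3' UTR
    utr3_len: int = 200
    site_offsets: tuple[int, ...] = ()  # true sites, bp past annotated 3' end
    decoy_offsets: tuple[int, ...] = ()  # internal-priming decoys
    reads_per_site: float = 25.0  # Poisson mean per replicate
    decoy_reads_per_site: float = 15.0
    n_replicates: int = 3
    background_rate: float = 0.02  # per base per replicate
    jitter: bool = True
    deterministic_counts: bool = False  # noise-free mode: exact counts, no jitter
    motif_distance: int = 19  # planted PAS 3' end -> site, bp upstream
    rnaseq_depth: float = 30.0
    rnaseq_window: int = 50
    lognormal_sigma: float = 0.8
    dropout_prob: float = 0.02
    planted_utr_gaps: tuple[tuple[int, int], ...] = ()  # (offset past end, length)
    est_error_rate: float = 0.1
    est_length: int = 500
    est_spacing: int = 350

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ScenarioError(f"unknown scenario {self.scenario!r}")
        if any(o <= 0 for o in self.site_offsets + self.decoy_offsets):
            raise ScenarioError("site offsets must be positive")
        end = self.annotated_end + max(
            self.site_offsets + self.decoy_offsets, default=0
        )
        if end + 100 > self.contig_length:
            raise ScenarioError(
                f"planted site at {end} exceeds contig length {self.contig_length}"
            )

    @property
    def gene_end(self) -> int:
        return (
            self.gene_start
            + self.exon1_len
            + self.intron_len
            + self.exon2_len
            - 1
        )

    @property
    def annotated_end(self) -> int:
        return self.gene_end


def make_spec(scenario: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Scenario presets encoding each worked-example class."""
    presets: dict[str, dict] = {
        "simple_extension": dict(
            site_offsets=(1_450, 1_900, 2_400, 4_200),
            planted_utr_gaps=((600, 25), (1_600, 30), (3_000, 20)),
        ),
        "ambiguous_multi_peak": dict(
            site_offsets=(1_500,),
            decoy_offsets=(100, 200, 300, 400),
        ),
        "curated_two_sites": dict(
            site_offsets=(5_000, 8_500),
        ),
        "long_extension_past_window": dict(
            site_offsets=(1_500,),
        ),
        "wrong_strand": dict(
            exon1_len=400, intron_len=0, exon2_len=0, utr5_len=100, utr3_len=50,
        ),
        "overlapping_convergent": dict(
            site_offsets=(),
        ),
        "overlapping_models_broad_peak": dict(
            site_offsets=(),
        ),
        "pri_mirna": dict(
            exon1_len=400, intron_len=0, exon2_len=0, utr5_len=100, utr3_len=50,
        ),
        "novel_short_feature": dict(
            site_offsets=(),
        ),
    }
    kw = presets[scenario] | overrides
    return ScenarioSpec(scenario=scenario, seed=seed, **kw)


@dataclass
class ScenarioTruth:
    """Planted features and the endpoints the pipeline should reach."""

    scenario: str
    seed: int
    contig: str
    strand: str
    annotated_end: int
    true_sites: list[int] = field(default_factory=list)
    decoy_sites: list[int] = field(default_factory=list)
    opposite_sites: list[int] = field(default_factory=list)
    planted_gaps: list[list[int]] = field(default_factory=list)  # [start, end]
    arm_pairs: list[dict] = field(default_factory=list)
    pri_mirna_three_prime: int | None = None
    short_feature_peak: list[int] | None = None
    expected_endpoint: str | None = None
    expected_node_path: list[int] | None = None
    expected_endpoint_stranded: str | None = None
    expected_node_path_stranded: list[int] | None = None
    expected_endpoint_baseline: str | None = None
    expected_accepted_sites: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# sequence assembly helpers


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


_BASES = np.array(list("ACGT"))


def _plant(seq: list[str], pos: int, motif: str) -> None:
    """Overwrite seq (1-based position of motif's first base)."""
    seq[pos - 1 : pos - 1 + len(motif)] = list(motif)


# fixed geometry for the two sRNA scenarios (1-based coordinates)
_PRI_ARM_PAIRS = (
    ((5_000, 5_021, 100.0), (5_055, 5_076, 900.0)),
    ((5_200, 5_221, 120.0), (5_260, 5_281, 950.0)),
)
_PRI_FLANK_BLOCKS = ((4_800, 4_980), (5_091, 5_195), (5_291, 5_400))
_PRI_CLUSTER_POS = 5_481  # ~200 bp downstream of the 3'-most arm
_NOVEL_SEPARATION = 300  # zero-coverage bp between gene end and the block
_NOVEL_BLOCK_LEN = 600


def _novel_geometry(spec: ScenarioSpec):
    block_start = spec.annotated_end + _NOVEL_SEPARATION + 1
    block = (block_start, block_start + _NOVEL_BLOCK_LEN - 1)
    drs_sites = (block_start + 100, block_start + 250, block_start + 400)
    srna_peak = (block_start + 180, block_start + 259)  # 80 bp footprint
    return block, drs_sites, srna_peak


def _build_genome(spec: ScenarioSpec, rng: np.random.Generator) -> str:
    seq = list("".join(_BASES[_random_bases(rng, spec.contig_length)]))
    end = spec.annotated_end
    for off in spec.site_offsets:
        site = end + off
        # PAS hexamer whose 3'-most base lies motif_distance bp upstream
        motif_start = site - spec.motif_distance - 5
        _plant(seq, motif_start, "AATAAA")
        _plant(seq, site + 1, _SITE_DOWNSTREAM_PAD)  # keep priming check clean
    for off in spec.decoy_offsets:
        site = end + off
        _plant(seq, site - len(_DECOY_UPSTREAM_PAD), _DECOY_UPSTREAM_PAD)
        _plant(seq, site + 1, _DECOY_A_RUN)
    if spec.scenario == "wrong_strand":
        _plant(seq, spec.gene_start + 150, _OPPOSITE_STOP_PLANT)
    if spec.scenario == "overlapping_models_broad_peak":
        _plant(seq, end - 120, "AT" * 40)  # strongly AT-rich upstream window
        _plant(seq, end - 25, "AATAAA")  # PAS 19 bp upstream of the end
        _plant(seq, end + 1, _SITE_DOWNSTREAM_PAD)
    if spec.scenario == "overlapping_convergent":
        _plant(seq, end - 25, "AATAAA")
        _plant(seq, end + 1, _SITE_DOWNSTREAM_PAD)
    if spec.scenario == "pri_mirna":
        # tandem PAS 26 bp upstream of the planted downstream cleavage site
        site = _PRI_CLUSTER_POS
        _plant(seq, site - 26 - 9, "AATAAATAAA")
        _plant(seq, site + 1, _SITE_DOWNSTREAM_PAD)
    if spec.scenario == "novel_short_feature":
        _, drs_sites, _ = _novel_geometry(spec)
        for site in drs_sites:
            _plant(seq, site - spec.motif_distance - 5, "AATAAA")
            _plant(seq, site + 1, _SITE_DOWNSTREAM_PAD)
    return "".join(seq)


# --------------------------------------------------------------------------
# track generation


def _jittered_positions(
    rng: np.random.Generator, site: int, n: int, jitter: bool
) -> np.ndarray:
    if not jitter or n == 0:
        return np.full(n, site)
    offs = rng.choice(_JITTER_OFFSETS, size=n, p=_JITTER_WEIGHTS)
    return site + offs


def _drs_counts(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    sites: list[tuple[int, str, float]],
) -> list[dict[str, dict[int, int]]]:
    """Per-replicate {strand: {pos: count}} maps."""
    reps: list[dict[str, dict[int, int]]] = []
    for _ in range(spec.n_replicates):
        counts: dict[str, dict[int, int]] = {"+": {}, "-": {}}
        for site, strand, mean in sites:
            if spec.deterministic_counts:
                counts[strand][site] = counts[strand].get(site, 0) + round(mean)
                continue
            n = int(rng.poisson(mean))
            jitter = spec.jitter and not spec.deterministic_counts
            for pos in _jittered_positions(rng, site, n, jitter):
                counts[strand][int(pos)] = counts[strand].get(int(pos), 0) + 1
        for strand in "+-":
            n_bg = int(rng.poisson(spec.background_rate * spec.contig_length / 2))
            if n_bg:
                for pos in rng.integers(1, spec.contig_length + 1, size=n_bg):
                    counts[strand][int(pos)] = counts[strand].get(int(pos), 0) + 1
        reps.append(counts)
    return reps


def _rnaseq_depth(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    covered: list[tuple[int, int]],
    zero_gaps: list[tuple[int, int]],
) -> np.ndarray:
    """Dense per-base depth (index 0 = position 1)."""
    depth = np.zeros(spec.contig_length, dtype=int)
    prev_dropout = False
    for lo, hi in covered:
        for wstart in range(lo, hi + 1, spec.rnaseq_window):
            wend = min(wstart + spec.rnaseq_window - 1, hi)
            dropout = (
                wend <= spec.annotated_end
                and not prev_dropout
                and rng.random() < spec.dropout_prob
            )
            prev_dropout = dropout
            if dropout:
                continue
            mult = rng.lognormal(0.0, spec.lognormal_sigma)
            level = max(1, int(rng.poisson(spec.rnaseq_depth * mult)))
            depth[wstart - 1 : wend] = level
    for lo, hi in zero_gaps:
        depth[lo - 1 : hi] = 0
    return depth


def _est_intervals(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    lo: int,
    hi: int,
    must_cover: list[tuple[int, int]],
    strand: str,
) -> list[tuple[int, int, str]]:
    ests = []
    pos = lo
    while pos + spec.est_length <= hi:
        est_strand = strand
        if rng.random() < spec.est_error_rate:
            est_strand = "-" if strand == "+" else "+"
        ests.append((pos, pos + spec.est_length - 1, est_strand))
        pos += spec.est_length + spec.est_spacing
    for glo, ghi in must_cover:
        mid = (glo + ghi) // 2
        ests.append(
            (mid - spec.est_length // 2, mid + spec.est_length // 2, strand)
        )
    return sorted(ests)


# --------------------------------------------------------------------------
# writers (all plain text, deterministic)


def _write_fasta(path: Path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")


def _write_gff3(path: Path, spec: ScenarioSpec, genes) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, strand, feats in genes:
            span_lo = min(s for _, s, _ in feats)
            span_hi = max(e for _, _, e in feats)
            fh.write(
                f"{spec.contig}\tpolyanno_sim\tgene\t{span_lo}\t{span_hi}\t.\t"
                f"{strand}\t.\tID={gene_id}\n"
            )
            fh.write(
                f"{spec.contig}\tpolyanno_sim\tmRNA\t{span_lo}\t{span_hi}\t.\t"
                f"{strand}\t.\tID={gene_id}.1;Parent={gene_id}\n"
            )
            for ftype, s, e in feats:
                fh.write(
                    f"{spec.contig}\tpolyanno_sim\t{ftype}\t{s}\t{e}\t.\t"
                    f"{strand}\t.\tParent={gene_id}.1\n"
                )


def _write_count_bedgraph(path: Path, contig: str, counts: dict[int, int]) -> None:
    with open(path, "w") as fh:
        for pos in sorted(counts):
            fh.write(f"{contig}\t{pos - 1}\t{pos}\t{counts[pos]}\n")


def _write_depth_bedgraph(path: Path, contig: str, depth: np.ndarray) -> None:
    with open(path, "w") as fh:
        n = len(depth)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and depth[j + 1] == depth[i]:
                j += 1
            if depth[i] > 0:
                fh.write(f"{contig}\t{i}\t{j + 1}\t{int(depth[i])}\n")
            i = j + 1


def _write_junctions_bed(path: Path, contig: str, introns, count: int = 15) -> None:
    with open(path, "w") as fh:
        for k, (s, e) in enumerate(introns, 1):
            fh.write(f"{contig}\t{s - 1}\t{e}\tjunc_{k}\t{count}\t+\n")


def _write_est_bed12(path: Path, contig: str, ests) -> None:
    with open(path, "w") as fh:
        for k, (s, e, strand) in enumerate(ests, 1):
            bs, be = s - 1, e
            fh.write(
                f"{contig}\t{bs}\t{be}\tEST_{k}\t0\t{strand}\t{bs}\t{be}\t0\t1\t"
                f"{be - bs},\t0,\n"
            )


# --------------------------------------------------------------------------
# scenario assembly


def generate_scenario(spec: ScenarioSpec, outdir: str | Path) -> ScenarioTruth:
    """Write one scenario directory; returns (and writes) the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    end = spec.annotated_end
    strand = "+"

    genome = _build_genome(spec, rng)

    # annotation: one gene, plus a convergent partner where the scenario
    # calls for one
    feats = _gene_feats(spec)
    genes = [("geneA", strand, feats)]
    if spec.scenario == "overlapping_convergent":
        b_lo, b_hi = end + 800, end + 2_800
        genes.append(
            ("geneB", "-", [("exon", b_lo, b_hi), ("three_prime_UTR", b_lo, b_lo + 199)])
        )

    # DRS sites: (position, strand, mean reads per replicate)
    sites: list[tuple[int, str, float]] = []
    truth = ScenarioTruth(
        scenario=spec.scenario,
        seed=spec.seed,
        contig=spec.contig,
        strand=strand,
        annotated_end=end,
    )
    for off in spec.site_offsets:
        # the most distal site is the dominant transcript form, as seen in
        # the worked re-annotation loci, and anchors the terminus check
        mean = spec.reads_per_site * (
            1.5 if off == max(spec.site_offsets) else 1.0
        )
        sites.append((end + off, strand, mean))
        truth.true_sites.append(end + off)
    for off in spec.decoy_offsets:
        sites.append((end + off, strand, spec.decoy_reads_per_site))
        truth.decoy_sites.append(end + off)

    covered = [(spec.gene_start, end)]
    zero_gaps: list[tuple[int, int]] = []
    est_hi = end
    must_cover: list[tuple[int, int]] = []

    if spec.site_offsets:
        distal = end + max(spec.site_offsets)
        covered = [(spec.gene_start, distal + 1)]
        est_hi = distal
        for gap_off, gap_len in spec.planted_utr_gaps:
            glo = end + gap_off
            ghi = glo + gap_len - 1
            zero_gaps.append((glo, ghi))
            must_cover.append((glo, ghi))
            truth.planted_gaps.append([glo, ghi])

    if spec.scenario == "wrong_strand":
        # broad (~20 bp) reverse-strand peak at the start of the annotated
        # 5' UTR: several adjacent cleavage positions, each well covered
        opp_sites = [spec.gene_start + 4 + k * 3 for k in range(7)]
        for pos in opp_sites:
            sites.append((pos, "-", 15.0))
            truth.opposite_sites.append(pos)
        truth.expected_endpoint = "negative_inconsistent"
        truth.expected_node_path = [1, 2, 3, 9, 10, 11, 12]
        truth.expected_endpoint_stranded = "tentative_opposite_strand"
        truth.expected_node_path_stranded = [1, 2, 3, 9, 10, 13, 14, 15]

    if spec.scenario in ("overlapping_convergent", "overlapping_models_broad_peak"):
        if spec.scenario == "overlapping_models_broad_peak":
            # broad ~20 bp peak: many adjacent cleavage positions whose
            # usage rises toward the annotated end (AT-rich, imprecise site)
            for k in range(7):
                sites.append((end - 18 + 3 * k, strand, 6.0 + 2.5 * k))
            truth.true_sites.append(end)
        else:
            sites.append((end, strand, spec.reads_per_site))
            b_lo = end + 800
            sites.append((b_lo, "-", spec.reads_per_site))
            truth.true_sites.append(end)
            covered = [(spec.gene_start, end), (b_lo, end + 2_800)]
        truth.expected_endpoint = "positive_structure_confirmed"

    if spec.scenario == "pri_mirna":
        sites.append((_PRI_CLUSTER_POS, "+", spec.reads_per_site))
        covered = [(spec.gene_start, end)] + [list(b) for b in _PRI_FLANK_BLOCKS]
        covered = [tuple(c) for c in covered]
        # extend the final flank up to the downstream cleavage cluster
        covered[-1] = (_PRI_FLANK_BLOCKS[-1][0], _PRI_CLUSTER_POS + 1)
        truth.pri_mirna_three_prime = _PRI_CLUSTER_POS
        for (a_lo, a_hi, a_h), (b_lo, b_hi, b_h) in _PRI_ARM_PAIRS:
            truth.arm_pairs.append(
                {
                    "five_p": [a_lo, a_hi],
                    "three_p": [b_lo, b_hi],
                    "dominant": "3p" if b_h > a_h else "5p",
                }
            )

    if spec.scenario == "novel_short_feature":
        block, drs_sites, srna_peak = _novel_geometry(spec)
        for pos in drs_sites:
            sites.append((pos, strand, spec.reads_per_site))
        covered = [(spec.gene_start, end), block]
        truth.short_feature_peak = list(srna_peak)
        truth.true_sites.extend(drs_sites)
        truth.expected_endpoint = "tentative_novel_feature"
        truth.expected_node_path = [1, 2, 3, 4, 18]

    if spec.scenario in (
        "simple_extension",
        "ambiguous_multi_peak",
        "curated_two_sites",
        "long_extension_past_window",
    ):
        truth.expected_endpoint = "positive_extension"
        truth.expected_node_path = [1, 2, 3, 4, 5, 6, 7, 8]
        truth.expected_accepted_sites = list(truth.true_sites)
        if spec.scenario == "long_extension_past_window":
            truth.expected_endpoint_baseline = "negative_insufficient"

    # ---- draw the data
    drs_reps = _drs_counts(spec, rng, sites)
    rnaseq = _rnaseq_depth(spec, rng, covered, zero_gaps)
    ests = _est_intervals(
        spec, rng, spec.gene_start, est_hi, must_cover, strand
    )
    srna = np.zeros(spec.contig_length, dtype=float)
    if spec.scenario == "pri_mirna":
        for pair in _PRI_ARM_PAIRS:
            for lo, hi, h in pair:
                srna[lo - 1 : hi] = h
    if spec.scenario == "novel_short_feature":
        _, _, srna_peak = _novel_geometry(spec)
        srna[srna_peak[0] - 1 : srna_peak[1]] = 500.0

    # ---- write everything
    _write_fasta(outdir / "genome.fa", spec.contig, genome)
    _write_gff3(outdir / "annotation.gff3", spec, genes)
    for i, counts in enumerate(drs_reps, 1):
        _write_count_bedgraph(
            outdir / f"drs_rep{i}_plus.bedgraph", spec.contig, counts["+"]
        )
        _write_count_bedgraph(
            outdir / f"drs_rep{i}_minus.bedgraph", spec.contig, counts["-"]
        )
    _write_depth_bedgraph(outdir / "rnaseq.bedgraph", spec.contig, rnaseq)
    _write_junctions_bed(
        outdir / "junctions.bed", spec.contig, _annotated_introns(spec)
    )
    _write_est_bed12(outdir / "est.bed12", spec.contig, ests)
    _write_depth_bedgraph(outdir / "srna.bedgraph", spec.contig, srna)
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    return truth


def _gene_feats(spec: ScenarioSpec):
    s = spec.gene_start
    feats = [("five_prime_UTR", s, s + spec.utr5_len - 1)]
    e1_hi = s + spec.exon1_len - 1
    feats.append(("exon", s, e1_hi))
    if spec.intron_len:
        feats.append(("intron", e1_hi + 1, e1_hi + spec.intron_len))
        e2_lo = e1_hi + spec.intron_len + 1
    else:
        e2_lo = None
    if spec.exon2_len:
        feats.append(("exon", e2_lo, e2_lo + spec.exon2_len - 1))
    end = spec.gene_end
    feats.append(("three_prime_UTR", end - spec.utr3_len + 1, end))
    return feats


def _annotated_introns(spec: ScenarioSpec):
    if not spec.intron_len:
        return []
    lo = spec.gene_start + spec.exon1_len
    return [(lo, lo + spec.intron_len - 1)]


def emit_fixture_suite(outdir: str | Path, base_seed: int = 0) -> dict:
    """Emit all nine scenario directories plus a manifest with checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"base_seed": base_seed, "scenarios": {}}
    for i, name in enumerate(SCENARIOS):
        seed = base_seed * 1_000 + i
        sdir = outdir / name
        truth = generate_scenario(make_spec(name, seed=seed), sdir)
        checksums = {}
        for f in sorted(sdir.iterdir()):
            if f.name.endswith(".fai"):
                continue
            checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        manifest["scenarios"][name] = {
            "seed": seed,
            "expected_endpoint": truth.expected_endpoint,
            "checksums": checksums,
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
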