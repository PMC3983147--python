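# Methods

`polyanno` automates the combined-evidence interpretation step that sits
between raw transcriptomic tracks and a revised gene annotation.  The
inputs are the four data types a curator would load into a genome
browser — strand-specific 3'-end sequencing (which reads the genomic
position of cleavage/polyadenylation to roughly ±2 bp and natively reports
the transcribed strand), un-stranded short-read RNA-seq coverage with
splice junctions, archival ESTs (informative for transcript extent but
with untrustworthy strand flags), and small-RNA-seq coverage — plus the
genome sequence and the current annotation.  The output is, per locus, a
decision with an explicit audit trail and, where warranted, a concrete
re-annotation proposal.

## Peak calling from 3'-end tracks

Each retained sequencing read contributes one count at its 3'-terminal
aligned base (highest aligned coordinate on the forward strand, lowest on
the reverse).  Alignment-level filters: unique mappings only (primary
alignment, mapping quality ≥ 20, `NH` ≤ 1 when present), at most 3
insertion/deletion events in the CIGAR, and read length ≥ 25 bases.  The
indel rule counts CIGAR I/D *events*; read length uses an inclusive ≥.

Position-level filter: a genomic position is kept only when it carries at
least `min_reads_per_replicate` reads (default 3) in *every* replicate
(default: all replicates required).  Under Poisson counting statistics the
signal-to-noise ratio of a position with total count *N* is
*N*/√*N* = √*N*, so the weakest retained signal (3 reads in each of 3
replicates) has S/N = √9 = 3; `snr_min` (default 3.0) is enforced as a
floor.  Single-replicate datasets instead use `singleton_mode`, which
drops only positions supported by one read and applies no S/N floor.

Retained positions are clustered by single linkage with
`max_cluster_gap` = 25 bp (between the ~20 bp broad peaks and the 30 bp
multi-peak groupings seen in real loci).  A cluster's *mode* is its
highest-count position, ties broken toward the most 3' position in
transcription direction (consistently favouring the distal cleavage
position).  Sub-peaks are local maxima of the count profile; member
positions separated by uncovered bases are separate sub-peaks.

## Sequence checks at candidate sites

*Poly(A) signal.* Hexamers are scanned in transcription sense over a
window 10–40 bp upstream of the candidate cleavage position (covering the
observed 15–26 bp offsets with margin).  AATAAA within one mismatch is
accepted; exact ATTAAA and AATAAG are reported as named variants; the
tandem AATAAATAAA ten-mer is its own class.  The best hit minimizes
mismatches, then distance to 19 bp (the modal observed offset).  Windows
touching an ambiguous base (N) never produce a hit.  Whether mismatched
forms of the named variants should also count is undecidable from the
available descriptions; only exact named variants are accepted, and this
is an assumption.

*Internal priming.* Oligo-dT-free protocols are largely immune, but
candidate sites from any source can still sit on genomic adenosine
tracts.  A site is flagged when an A-run of ≥ 6 bases begins within 10 bp
downstream (transcription sense), or when the A fraction of that 10 bp
window reaches 0.7.  These thresholds are not stated anywhere in the
source material; they encode "long runs of adenosine immediately
downstream" and are configurable.

*Stop-codon profile and AT fraction.* TAA/TAG/TGA are counted per reading
frame on a chosen strand (strands computed independently); "multiple stop
codons" for the opposite-strand plausibility test means at least one stop
in *every* frame.  AT fraction excludes N from numerator and denominator
and flags all-N intervals as undefined.

## Coverage bridging

The extension between an annotated 3' end and a candidate cluster is
covered or it is not.  Gaps are maximal zero-depth runs; only runs of
`min_gap_len` = 50 bp or more are *significant* (shorter dropouts are
protocol artefacts).  The verdict for a candidate extension is:

- **continuous** — at least one evidence source individually shows no
  significant gap over the extension (then the union trivially has none);
- **gapped_but_bridged** — every source has significant gaps, but gaps in
  one source are covered by another and no unbridged union gap reaches
  `hard_fail_gap` = 500 bp;
- **unsupported** — an unbridged union run of ≥ 500 bp, or union coverage
  over less than 20% of the extension.

EST strand flags are ignored for bridging (they are unreliable) but
retained for reporting.  Un-stranded RNA-seq contributes to both strands.
The *terminus offset* is the transcript-sense distance from the last
covered base to the cluster mode, probed up to 50 bp past the mode so
coverage running far beyond a site is not mistaken for terminating there;
agreement within `terminus_tolerance` = 10 bp (1 bp observed in the
clean worked case, plus the ±2 bp positional accuracy with margin) counts
as coincident.

Junction support labels each annotated intron **supported** (≥ 3 reads
spanning its exact boundaries), **weak** (1–2) or **unsupported** (0);
the threshold of 3 is an assumption, no minimum being stated anywhere.
Junctions matching no annotated intron are reported as novel.

## The decision tree

Evidence per locus is pushed through a deterministic tree with eight
terminals: three positive (`positive_extension`,
`positive_structure_confirmed`, `positive_novel_model`), three tentative
(`tentative_extension`, `tentative_opposite_strand`,
`tentative_novel_feature`) and two negative (`negative_insufficient`,
`negative_inconsistent`).  Node ids 1–15 follow the two worked paths
through the reference curation flow diagram (1–8 for a clean extension;
1,2,3,9,10,11,12 and 1,2,3,9,10,13,14,15 for a wrong-strand locus without
and with stranded RNA-seq).  The diagram describes only those paths, so
the remaining terminals are a **reconstruction**, numbered 16–21 and kept
in a data table (`NODE_LABELS`) so predicates can be re-mapped without
code changes:

- 16 `positive_structure_confirmed`: no downstream clusters, but a
  cluster confirms the annotated 3' end within the terminus tolerance;
- 17 `negative_insufficient`: a required evidence layer is missing, named
  in the decision;
- 18 `tentative_novel_feature`: downstream expression separated from the
  gene end by ≥ `separation_min` = 100 bp of zero coverage (a spatial
  separation argues for a distinct downstream feature, not a longer UTR);
- 19 `tentative_extension`: extension supported but only gap-tolerated
  (`gapped_but_bridged`) or not terminating at an accepted site;
- 21 `positive_novel_model`: internal motif-supported clusters with
  intact junction support propose a shorter/internal model.

Node 5 ("evidence terminates near the strongest downstream cluster") is
anchored on the most distal *accepted* cluster: the question asked is
whether broad-coverage evidence ends at an accepted site, and in the
motivating loci the distal peak — where coverage ends — is also the
dominant one.  Site selection excludes priming-flagged clusters unless a
poly(A) motif supports them (then retained with a warning) and ranks the
rest by total count; every accepted cluster becomes an alternative
poly(A) site in the proposal, with the 3' UTR of each alternative ending
at that cluster's mode.

A `baseline_window` switch restricts the downstream search to a fixed
distance (e.g. 300 bp), reproducing the blind spots of window-limited
automated re-annotation; the default search extends `search_window` =
10 kb downstream (one observed extension needed ~8.5 kb).

## Small-RNA integration

Mature miRNAs appear as *pairs* of short peaks (arm footprint 18–25 bp)
separated by a loop-scale gap (10–60 bp); the higher arm is dominant
unless the height ratio is below 1.25 (then *balanced*).  None of these
three bounds is externally specified; they bracket canonical mature-miRNA
geometry and are configurable.  The pri-miRNA transcript is modelled as
the RNA-seq blocks flanking the zero-coverage hairpin-excision zones, its
3' end anchored at the 3'-end cluster up to 1 kb downstream of the
3'-most arm (open-ended and *tentative* when no cluster exists).  A
strong sRNA peak (≥ the 95th percentile of non-zero coverage in the
scanned region) that does **not** form an arm pair, coinciding with a
low-level RNA-seq block and at least two 3'-end clusters, is called a
short-feature candidate (snoRNA-like); an external prediction flag (e.g.
from a dedicated snoRNA predictor) is attached when provided, never
computed.  Arm-pair detection and short-feature calling are mutually
exclusive on the same peaks.  sRNA reads are treated as un-stranded.

## Synthetic loci and what they do (not) show

The generator emits complete mini-studies in standard text formats
(FASTA, GFF3, bedGraph, BED6/BED12, JSON truth), one per scenario class:
clean multi-site extension, priming-decoy ambiguity, curated two-site
locus, extension past the baseline window, wrong-strand annotation,
convergent overlapping genes, broad AT-rich peak, pri-miRNA, and a
separated novel short feature.

Noise model: 3'-end reads land at the true site plus discrete triangular
jitter on {−2…+2} (only the ±2 bound is externally stated; the triangular
shape is a choice); per-site per-replicate counts are Poisson with mean
25 (distal site 1.5×, mirroring the dominant distal forms seen in real
loci; 25 keeps every jittered sub-position reliably above the 3-read
floor).  Background is Poisson 0.02 reads/base/replicate — sized so the
replicate filter removes essentially all of it, which is that filter's
purpose.  RNA-seq coverage is piecewise-constant over 50 bp windows with
lognormal(σ = 0.8) multipliers, sub-threshold dropout windows (2%,
never adjacent, upstream of the annotated end only) and explicitly
planted zero gaps downstream; ESTs are sparse 500 bp intervals with a 10%
strand-flip rate, plus one EST over each planted gap.  Decoy sites get a
12-base A-run downstream and a guaranteed motif-free upstream pad;
true sites get a planted AATAAA ending 19 bp upstream and a non-A pad
downstream, so signal checks measure the planted truth rather than
accidents of the random sequence.

The generator does **not** simulate read-level sequencing errors,
alignment ambiguity, expression heterogeneity between loci, or chance
co-occurrence of motifs and priming tracts — so green tests demonstrate
that the *rules* behave as specified on data with the stated statistical
structure, not that the rules are sufficient for any real genome.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive; BED conversion is centralized in one
  function pair.  Table segment length is `end − start` (the convention
  that reproduces the published per-segment coverage values); summary
  lengths are segment sums, with the span stored separately because one
  published summary row follows the span convention instead (719 bp).
  Minus-strand rows supplied high-to-low are normalized on ingest with
  display order preserved for reports.
- Adjacent proposed segments may abut with a +1 offset or share a
  boundary coordinate (both occur in published tables); offset 0 warns,
  anything else is an error.
- Cluster-mode ties break toward the most 3' position; plateau sub-peaks
  count once; empty inputs yield empty outputs (never errors) in peak
  calling, gap finding and sRNA peak detection; an all-N interval has
  undefined AT fraction and is flagged; scans clipped by a contig edge
  warn rather than fail.
- Determinism: every stochastic step draws from one seeded
  `numpy.random.Generator`; identical spec + seed gives byte-identical
  files, and the pipeline itself is deterministic given its inputs.

## Problem sizes

Test fixtures use single loci on 14–22 kb contigs with three replicates,
and the statistical checks use 200 planted sites; these sizes make every
property of interest measurable (recovery accuracy, Poisson count
calibration, background rejection) while keeping the full suite under a
minute.

## Known limitations

- The reconstructed tree nodes 16–21 are a design interpretation; real
  curation is fuzzier than any fixed predicate set, which is precisely
  why the trail of per-node booleans is part of every decision.
- Stranded RNA-seq is consumed as an availability/confirmation flag, not
  as a track; integrating an actual stranded coverage pair is future
  work.
- 5'-end revision is carried through in proposals only descriptively; no
  TSS evidence is evaluated.
- EST exon structure is used for coverage only; implied EST splice
  junctions are not scored against the annotation.
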