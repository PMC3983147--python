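# polyanno

Combined-evidence re-annotation of gene 3' ends and complex loci.

Reference annotations routinely get transcript 3' ends wrong: 3' UTRs are
truncated or missing, overlapping genes on opposite strands are tangled
together, and window-limited automated re-annotators miss extensions that
lie a few hundred bases too far downstream.  Because a large share of
RNA-seq reads (and *all* reads from 3'-end sequencing protocols) fall in
the 3' UTR, these errors propagate directly into expression estimates.

`polyanno` is for computational biologists who have strand-specific
3'-end sequencing data (which locates cleavage/polyadenylation sites to
about ±2 bp and natively reports the strand) alongside conventional
RNA-seq, archival ESTs and small-RNA-seq, and want to turn that evidence
into auditable re-annotation decisions.  It implements:

- **Peak calling** on 3'-end count tracks: unique-mapping/indel/length
  read filters, a per-position replicate filter (≥ 3 reads in each of 3
  replicates, i.e. a Poisson signal-to-noise floor of N/√N = √9 = 3), and
  single-linkage clustering (25 bp gap) into candidate poly(A) sites with
  modes, sub-peaks and per-replicate counts.
- **Sequence checks**: AATAAA poly(A)-signal scan (≤ 1 mismatch, named
  variants ATTAAA/AATAAG, tandem AATAAATAAA) 10–40 bp upstream;
  internal-priming detection via downstream A-runs; per-frame stop-codon
  profiles; AT fraction.
- **Coverage bridging**: does RNA-seq/EST evidence connect the annotated
  3' end to a candidate cluster — continuous, gapped-but-bridged across
  sources, or unsupported — plus splice-junction concordance with the
  annotated intron/exon structure.
- **A decision tree** with eight terminals (3 positive / 3 tentative / 2
  negative) that records the node path and per-node booleans for every
  locus and emits concrete GFF3 proposals, one alternative transcript per
  accepted poly(A) site.
- **Small-RNA integration**: 5p/3p miRNA arm-pair detection with
  dominant-arm calls, pri-miRNA delineation from flanking RNA-seq blocks,
  and novel short-feature (snoRNA-like) candidates.
- **A synthetic-locus generator** that emits nine scenario classes as
  standard text formats (FASTA/GFF3/bedGraph/BED/JSON truth) with full
  ground truth, so every stage is testable without any sequencing data.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Generate a synthetic locus in which a gene's annotated 3' end is followed
by four genuine downstream poly(A) sites, then run the pipeline:

```sh
polyanno simulate --scenario simple_extension --seed 7 --out demo/locus
polyanno annotate --scenario-dir demo/locus --out-dir demo/out
polyanno report --annotate-dir demo/out
```

prints:

```
== geneA.1 ==
endpoint: positive_extension (positive)
node path: 1 -> 2 -> 3 -> 4 -> 5 -> 6 -> 7 -> 8
  [ 1] load locus evidence: -
  [ 2] existing intron/exon structure supported: yes
  [ 3] same-strand DRS clusters downstream: yes
  [ 4] RNA-seq/EST evidence extends beyond annotation (contiguously): yes
  [ 5] evidence terminates near strongest accepted cluster: yes
  [ 6] continuous (or multi-source bridged) coverage over extension: yes
  [ 7] no contradicting sequence features at accepted sites: yes
  [ 8] terminal: positive_extension: -
clusters: 8400, 5650, 6100, 6599
proposal: geneA 2001-8400 (+) summary 6398 bp over 4 alternative model(s)
```

Reading this: the splice junctions support the existing gene structure
(node 2); replicate-supported 3'-end clusters exist downstream of the
annotated end at positions 5650, 6100, 6599 and 8400 — within 2 bp of the
planted truth (5650/6100/6600/8400, the generator jitters read ends by up
to ±2 bp); RNA-seq coverage runs contiguously from the gene to 1 bp past
the most distal cluster (nodes 4–6); every accepted site has a canonical
poly(A) motif and no internal-priming signature (node 7).  The result is
a positive re-annotation: four alternative transcripts whose 3' UTRs end
at the four cluster modes, written to `demo/out/proposals.gff3`, with the
decision trail in `demo/out/decisions.tsv`.

The scenario classes cover the harder cases too: `wrong_strand` (the
gene's expression is really on the opposite strand — negative without
stranded RNA-seq, a tentative strand flip with it, via
`--stranded-rnaseq`), `long_extension_past_window` (found by the default
10 kb search but missed with `--baseline-window 300`), `pri_mirna`,
`novel_short_feature`, and others; `polyanno simulate --out DIR` writes
the full nine-scenario suite with a checksum manifest.

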