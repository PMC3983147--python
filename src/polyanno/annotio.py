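"""Reading and writing gene annotations (GFF3, GTF, BED12, TSV report).

GFF3/GTF parsing is delegated to :mod:`gffutils` (in-memory database);
BED12 lines are converted directly.  The TSV writer reproduces the layout
of the annotation comparison tables: label, chromosome, start, end, strand
and table-convention coverage, with minus-strand rows printed in their
original display orientation.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import GenomeInterval, from_bed_coords
from .models import GeneModel, ReannotationRecord, StructuralError

_GFF_ROLE_MAP = {
    "five_prime_utr": "five_prime_utr",
    "five_prime_UTR": "five_prime_utr",
    "three_prime_utr": "three_prime_utr",
    "three_prime_UTR": "three_prime_utr",
    "exon": "exon",
    "intron": "intron",
    "CDS": "body",
}
_ROLE_GFF_TYPE = {
    "five_prime_utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
    "body": "CDS",
    "exon": "exon",
    "intron": "intron",
}


class AnnotationParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def read_annotations(path: str | Path, format: str = "GFF3") -> list[GeneModel]:
    """Read gene models from a GFF3, GTF or BED12 file."""
    fmt = format.upper()
    if fmt in ("GFF3", "GTF"):
        return _read_gff(path, dialect="gtf" if fmt == "GTF" else "gff3")
    if fmt == "BED12":
        return _read_bed12(path)
    raise ValueError(f"unsupported annotation format {format!r}")


def _read_gff(path: str | Path, dialect: str) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    transcript_types = ("mRNA", "transcript")
    seen_transcripts = set()
    for ttype in transcript_types:
        for tr in db.features_of_type(ttype, order_by="start"):
            if tr.id in seen_transcripts:
                continue
            seen_transcripts.add(tr.id)
            segments: list[tuple[str, GenomeInterval]] = []
            for child in db.children(tr, order_by="start"):
                role = _GFF_ROLE_MAP.get(child.featuretype)
                if role is None:
                    continue
                segments.append(
                    (role, GenomeInterval(child.seqid, child.start, child.end, tr.strand))
                )
            if not segments:
                segments = [
                    ("exon", GenomeInterval(tr.seqid, tr.start, tr.end, tr.strand))
                ]
            parents = list(db.parents(tr, featuretype="gene"))
            gene_id = parents[0].id if parents else tr.attributes.get(
                "gene_id", [tr.id]
            )[0]
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tr.id,
                    source="primary-db",
                    segments=segments,
                    strand=tr.strand,
                )
            )
    return models


def _read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(
                    f"expected 12 BED fields, got {len(fields)}", lineno
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(str(exc), lineno) from exc
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise AnnotationParseError("block count mismatch", lineno)
            segments = [
                (
                    "exon",
                    from_bed_coords(
                        chrom,
                        chrom_start + bstart,
                        chrom_start + bstart + bsize,
                        strand,
                    ),
                )
                for bstart, bsize in zip(block_starts, block_sizes)
            ]
            models.append(
                GeneModel(
                    gene_id=name,
                    transcript_id=name,
                    source="primary-db",
                    segments=segments,
                    strand=strand if strand in "+-" else ".",
                )
            )
    return models


def write_annotations(
    records: Sequence[GeneModel | ReannotationRecord],
    path: str | Path,
    format: str = "GFF3",
) -> None:
    """Write gene models or re-annotation records as GFF3 or a TSV table."""
    fmt = format.upper()
    if fmt == "GFF3":
        _write_gff3(records, path)
    elif fmt in ("TSV", "TSV-TABLE"):
        _write_tsv(records, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


def _iter_models(
    records: Iterable[GeneModel | ReannotationRecord],
) -> Iterable[GeneModel]:
    for rec in records:
        if isinstance(rec, ReannotationRecord):
            yield from rec.alternatives
        else:
            yield rec


def _write_gff3(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in _iter_models(records):
            span = model.span
            fh.write(
                "\t".join(
                    [
                        span.chrom,
                        "polyanno",
                        "mRNA",
                        str(span.start),
                        str(span.end),
                        ".",
                        model.strand,
                        ".",
                        f"ID={model.transcript_id};gene_id={model.gene_id}",
                    ]
                )
                + "\n"
            )
            for role, iv in model.segments:
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "polyanno",
                            _ROLE_GFF_TYPE[role],
                            str(iv.start),
                            str(iv.end),
                            ".",
                            model.strand,
                            ".",
                            f"Parent={model.transcript_id}",
                        ]
                    )
                    + "\n"
                )


_TSV_HEADER = ["Annotation", "Chr", "Start (bp)", "End (bp)", "Strand", "Coverage (bp)"]


def _write_tsv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for rec in records:
            if isinstance(rec, ReannotationRecord):
                for model in rec.alternatives:
                    for role, iv in model.segments:
                        a, b = iv.display_coords
                        writer.writerow(
                            [
                                f"{model.transcript_id}: {role}",
                                iv.chrom,
                                a,
                                b,
                                model.strand,
                                iv.table_length,
                            ]
                        )
                a, b = rec.summary_interval.display_coords
                writer.writerow(
                    [
                        "Summary",
                        rec.summary_interval.chrom,
                        a,
                        b,
                        rec.strand,
                        rec.summary_length_bp,
                    ]
                )
            else:
                for role, iv in rec.segments:
                    a, b = iv.display_coords
                    writer.writerow(
                        [
                            f"{rec.transcript_id}: {role}",
                            iv.chrom,
                            a,
                            b,
                            rec.strand,
                            iv.table_length,
                        ]
                    )


def roundtrip_gff3(records, path) -> list[GeneModel]:
    """Write records as GFF3 and read them back (coordinate round-trip)."""
    _write_gff3(records, path)
    return read_annotations(path, "GFF3")
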