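"""GTF and FASTA I/O plus transcript sequence extraction.

GTF files use 1-based inclusive coordinates; everything downstream of
:func:`parse_gtf` uses the package's 0-based half-open convention, so the
conversion lives only here.  Attribute parsing of each GTF line is
delegated to :mod:`gffutils`; this module keeps track of line numbers so
parse errors point at the offending record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

from .models import (
    ANNOTATED_LNCRNA,
    CODING,
    UNANNOTATED,
    AnnotationError,
    ExonInterval,
    GenomeAnnotation,
    SequenceRecord,
    TranscriptModel,
)

PathLike = Union[str, Path]

#: default prefix StringTie-style merged assemblies give novel transcripts
NOVEL_ID_PREFIX = "MSTRG."

# biotype attribute values mapped to annotation statuses
_LNCRNA_BIOTYPE_KEYWORDS = ("lncrna", "lincrna", "antisense")
_BIOTYPE_ATTRIBUTES = (
    "gene_biotype",
    "transcript_biotype",
    "gene_type",
    "transcript_type",
)


class GtfParseError(AnnotationError):
    """A malformed GTF record; the message names the line number."""


def default_biotype_rules(attributes: Mapping[str, str]) -> str:
    """Map GTF attributes to an annotation status.

    ``protein_coding`` biotypes are coding; biotypes mentioning
    lncRNA/lincRNA/antisense are annotated lncRNAs; anything without a
    recognized biotype is unannotated (novel-assembly convention).
    """
    for key in _BIOTYPE_ATTRIBUTES:
        value = attributes.get(key)
        if value is None:
            continue
        lowered = value.lower()
        if lowered == "protein_coding":
            return CODING
        if any(k in lowered for k in _LNCRNA_BIOTYPE_KEYWORDS):
            return ANNOTATED_LNCRNA
    return UNANNOTATED


def parse_gtf(
    path: PathLike,
    biotype_rules: Callable[[Mapping[str, str]], str] = default_biotype_rules,
) -> GenomeAnnotation:
    """Read a GTF file into a :class:`GenomeAnnotation`.

    Only ``exon`` features are consumed; transcript models are assembled
    from their exon lines.  Coordinates are converted from GTF 1-based
    inclusive to internal 0-based half-open.
    """
    exons: Dict[str, List[ExonInterval]] = {}
    genes: Dict[str, str] = {}
    statuses: Dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                feature = feature_from_line(line)
                start_1b, end_1b = int(fields[3]), int(fields[4])
            except Exception as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: malformed GTF record ({exc})"
                ) from exc
            attrs = {k: v[0] for k, v in feature.attributes.items() if v}
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon without transcript_id"
                )
            gid = attrs.get("gene_id", tid)
            if feature.strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path}: line {lineno}: exon of {tid} lacks a strand"
                )
            try:
                exon = ExonInterval(
                    chrom=feature.seqid,
                    start=start_1b - 1,
                    end=end_1b,
                    strand=feature.strand,
                )
            except AnnotationError as exc:
                raise GtfParseError(f"{path}: line {lineno}: {exc}") from exc
            exons.setdefault(tid, []).append(exon)
            genes.setdefault(tid, gid)
            if tid not in statuses:
                statuses[tid] = biotype_rules(attrs)

    annotation = GenomeAnnotation()
    for tid, exon_list in exons.items():
        annotation.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                exons=tuple(exon_list),
                annotation_status=statuses[tid],
            )
        )
    return annotation


_STATUS_BIOTYPE = {
    CODING: "protein_coding",
    ANNOTATED_LNCRNA: "lncRNA",
    UNANNOTATED: None,
}


def write_gtf(annotation: GenomeAnnotation, path: PathLike) -> None:
    """Write an annotation as GTF (1-based inclusive, Ensembl attributes).

    ``parse_gtf(write_gtf(a))`` reproduces ``a`` exactly, including
    annotation statuses (encoded through ``gene_biotype``).
    """
    with open(path, "w") as handle:
        handle.write("#!adipolnc GTF export\n")
        for t in sorted(
            annotation, key=lambda t: (t.chrom, t.span, t.transcript_id)
        ):
            biotype = _STATUS_BIOTYPE[t.annotation_status]
            for e in t.exons:
                attrs = f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}";'
                if biotype is not None:
                    attrs += f' gene_biotype "{biotype}";'
                handle.write(
                    f"{e.chrom}\tadipolnc\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: PathLike) -> Dict[str, SequenceRecord]:
    """Read a FASTA file into a dict of SequenceRecords keyed by id."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = SequenceRecord(id=rec.id, sequence=str(rec.seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: PathLike, width: int = 70
) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def extract_transcript_sequence(
    genome: Mapping[str, SequenceRecord], transcript: TranscriptModel
) -> SequenceRecord:
    """Spliced transcript sequence: exons concatenated in genomic order,
    reverse-complemented for minus-strand transcripts."""
    if transcript.chrom not in genome:
        raise AnnotationError(
            f"{transcript.transcript_id}: chromosome {transcript.chrom!r} "
            "not in genome"
        )
    chrom_seq = genome[transcript.chrom].sequence
    pieces = []
    for e in transcript.exons:
        if e.end > len(chrom_seq):
            raise AnnotationError(
                f"{transcript.transcript_id}: exon [{e.start},{e.end}) beyond "
                f"end of {transcript.chrom} (length {len(chrom_seq)})"
            )
        pieces.append(chrom_seq[e.start : e.end])
    seq = "".join(pieces)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return SequenceRecord(id=transcript.transcript_id, sequence=seq)


def extract_all_sequences(
    genome: Mapping[str, SequenceRecord], annotation: GenomeAnnotation
) -> Dict[str, SequenceRecord]:
    return {
        t.transcript_id: extract_transcript_sequence(genome, t)
        for t in annotation
    }
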