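"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based, half-open throughout the package; GTF I/O
converts to and from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from intervaltree import IntervalTree

# Annotation status values a transcript can carry.
CODING = "coding"
ANNOTATED_LNCRNA = "annotated_lncRNA"
UNANNOTATED = "unannotated"
ANNOTATION_STATUSES = (CODING, ANNOTATED_LNCRNA, UNANNOTATED)

VALID_STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised when an annotation object violates its invariants."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A single exon: 0-based half-open interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid exon interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered disjoint exons on a single chromosome/strand."""

    transcript_id: str
    gene_id: str
    exons: Tuple[ExonInterval, ...]
    annotation_status: str = UNANNOTATED

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        if self.annotation_status not in ANNOTATION_STATUSES:
            raise AnnotationError(
                f"{self.transcript_id}: unknown annotation_status "
                f"{self.annotation_status!r}"
            )
        object.__setattr__(self, "exons", tuple(sorted(self.exons)))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Spliced transcript length in nt (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic locus span: first exon start to last exon end."""
        return self.exons[0].start, self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> List[Tuple[int, int]]:
        """Gaps between consecutive exons as 0-based half-open intervals."""
        return [
            (a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]


class GenomeAnnotation:
    """A collection of transcripts plus interval indexes for overlap queries.

    The exon index supports per-chromosome overlap queries; transcript spans
    are indexed separately for nearest-locus / distance queries.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: Dict[str, TranscriptModel] = {}
        self._exon_index: Optional[Dict[str, IntervalTree]] = None
        self._span_index: Optional[Dict[str, IntervalTree]] = None
        for t in transcripts:
            self.add(t)

    def add(self, transcript: TranscriptModel) -> None:
        if transcript.transcript_id in self._transcripts:
            raise AnnotationError(
                f"duplicate transcript_id {transcript.transcript_id!r}"
            )
        self._transcripts[transcript.transcript_id] = transcript
        self._exon_index = None
        self._span_index = None

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self._transcripts == other._transcripts

    @property
    def transcripts(self) -> Dict[str, TranscriptModel]:
        return dict(self._transcripts)

    def subset(self, statuses: Iterable[str]) -> "GenomeAnnotation":
        wanted = set(statuses)
        return GenomeAnnotation(
            t for t in self if t.annotation_status in wanted
        )

    def single_exon_transcripts(self) -> List[TranscriptModel]:
        return [t for t in self if t.n_exons == 1]

    @property
    def exon_index(self) -> Dict[str, IntervalTree]:
        if self._exon_index is None:
            index: Dict[str, IntervalTree] = {}
            for t in self:
                tree = index.setdefault(t.chrom, IntervalTree())
                for e in t.exons:
                    tree.addi(e.start, e.end, t.transcript_id)
            self._exon_index = index
        return self._exon_index

    @property
    def span_index(self) -> Dict[str, IntervalTree]:
        if self._span_index is None:
            index: Dict[str, IntervalTree] = {}
            for t in self:
                s, e = t.span
                index.setdefault(t.chrom, IntervalTree()).addi(
                    s, e, t.transcript_id
                )
            self._span_index = index
        return self._span_index

    def overlapping_exons(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> List[str]:
        """Transcript ids with >= 1 bp of exonic overlap with [start, end).

        If ``strand`` is given, only same-strand exons count.
        """
        tree = self.exon_index.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        if strand is not None:
            hits = {
                h for h in hits
                if self._transcripts[h.data].strand == strand
            }
        return sorted({h.data for h in hits})


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError(f"{self.id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)
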