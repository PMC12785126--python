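"""The novel-lncRNA identification cascade.

Unannotated transcripts from a merged assembly survive only if they are
(1) longer than 200 nt and expressed above 0.5 FPKM in at least one
sample, (2) free of any exonic overlap with known (coding or annotated
lncRNA) exons and more than 2 kb away from every known single-exon
transcript, and (3) scored below 0 by the coding-potential model.  All
threshold comparisons are strict.  Every candidate receives a
:class:`FilterDecision` so the funnel is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .expression import ExpressionMatrix
from .models import (
    ANNOTATED_LNCRNA,
    CODING,
    UNANNOTATED,
    GenomeAnnotation,
    TranscriptModel,
)

# funnel stages, in application order
STAGE_LENGTH_FPKM = "length_fpkm"
STAGE_OVERLAP = "overlap"
STAGE_DISTANCE = "distance"
STAGE_CODING = "coding"
STAGE_PASSED = "passed"
STAGES = (STAGE_LENGTH_FPKM, STAGE_OVERLAP, STAGE_DISTANCE, STAGE_CODING)

# failure-reason labels
REASON_SHORT = "length<=200"
REASON_LOW_FPKM = "fpkm<=0.5"
REASON_EXON_OVERLAP = "overlaps_known_exon"
REASON_NEAR_SINGLE_EXON = "within_2kb_of_single_exon"
REASON_CODING = "coding_score>=0"
REASON_FEW_EXONS = "too_few_exons"


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the identification cascade; all comparisons strict."""

    min_length: int = 200            # nt, pass requires length > min_length
    min_fpkm: float = 0.5            # pass requires FPKM > min_fpkm in >= 1 sample
    min_single_exon_distance: int = 2000  # bp, pass requires gap > this
    coding_score_max: float = 0.0    # pass requires score < this
    stranded_overlap: bool = False   # exon-overlap filter considers strand
    min_exons: Optional[int] = None  # optional exon-count filter (off by default)

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.min_fpkm <= 0:
            raise ValueError("length/FPKM thresholds must be positive")
        if self.min_single_exon_distance <= 0:
            raise ValueError("distance threshold must be positive")


@dataclass
class FilterDecision:
    """Audit record for one candidate transcript."""

    transcript_id: str
    stage_reached: str
    reasons: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.stage_reached == STAGE_PASSED

    def __post_init__(self) -> None:
        if self.passed and self.reasons:
            raise ValueError("passed decision cannot carry failure reasons")
        if not self.passed and not self.reasons:
            raise ValueError("failed decision must carry at least one reason")


def compute_fpkm(
    counts: ExpressionMatrix, lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Counts → FPKM with library size = per-sample column totals."""
    return counts.compute_fpkm(lengths)


def filter_length_fpkm(
    candidates: Sequence[TranscriptModel],
    fpkm: pd.DataFrame,
    thr: FilterThresholds = FilterThresholds(),
) -> Dict[str, List[str]]:
    """Length/expression criterion; returns failure reasons per candidate.

    Pass requires length > min_length AND max-over-samples FPKM > min_fpkm
    (both strict).  Returns {transcript_id: [reasons]} with an empty list
    for passing candidates.
    """
    missing = [t.transcript_id for t in candidates if t.transcript_id not in fpkm.index]
    if missing:
        raise KeyError(
            f"candidates missing from expression matrix: {missing[:5]}"
        )
    max_fpkm = fpkm.max(axis=1)
    out: Dict[str, List[str]] = {}
    for t in candidates:
        reasons = []
        if not t.length > thr.min_length:
            reasons.append(REASON_SHORT)
        if not max_fpkm[t.transcript_id] > thr.min_fpkm:
            reasons.append(REASON_LOW_FPKM)
        if thr.min_exons is not None and t.n_exons < thr.min_exons:
            reasons.append(REASON_FEW_EXONS)
        out[t.transcript_id] = reasons
    return out


def filter_known_overlap(
    candidates: Sequence[TranscriptModel],
    known: GenomeAnnotation,
    thr: FilterThresholds = FilterThresholds(),
) -> Dict[str, List[str]]:
    """Known-exon overlap criterion (>= 1 bp of shared exonic sequence).

    Strand-blind by default: an antisense overlap still disqualifies.
    ``known`` should index the exons of coding and annotated-lncRNA
    transcripts.
    """
    out: Dict[str, List[str]] = {}
    for t in candidates:
        strand = t.strand if thr.stranded_overlap else None
        hit = any(
            known.overlapping_exons(e.chrom, e.start, e.end, strand=strand)
            for e in t.exons
        )
        out[t.transcript_id] = [REASON_EXON_OVERLAP] if hit else []
    return out


def _span_gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Boundary-to-boundary gap in bp between two spans; 0 if they touch
    or overlap."""
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def filter_single_exon_distance(
    candidates: Sequence[TranscriptModel],
    known: GenomeAnnotation,
    thr: FilterThresholds = FilterThresholds(),
) -> Dict[str, List[str]]:
    """Single-exon clearance criterion.

    A candidate fails when the gap between its locus span and any known
    single-exon transcript on the same chromosome is <= the threshold
    (strictly more than 2 kb of clearance is required to pass).
    """
    single_exon_spans: Dict[str, List[Tuple[int, int]]] = {}
    for t in known.single_exon_transcripts():
        single_exon_spans.setdefault(t.chrom, []).append(t.span)
    out: Dict[str, List[str]] = {}
    for t in candidates:
        span = t.span
        near = any(
            _span_gap(span, other) <= thr.min_single_exon_distance
            for other in single_exon_spans.get(t.chrom, ())
        )
        out[t.transcript_id] = [REASON_NEAR_SINGLE_EXON] if near else []
    return out


def identify_novel_lncrnas(
    assembled: GenomeAnnotation,
    reference: GenomeAnnotation,
    counts: ExpressionMatrix,
    scorer: Callable[[TranscriptModel], float],
    thr: FilterThresholds = FilterThresholds(),
) -> Tuple[List[TranscriptModel], List[FilterDecision], Dict[str, int]]:
    """Run the full cascade over the unannotated transcripts.

    ``scorer`` maps a transcript to its signed coding-potential score
    (typically a fitted :class:`~adipolnc.coding_potential.CodingPotentialScorer`
    applied to the extracted transcript sequence).

    Returns (novel transcripts, one decision per candidate, funnel counts).
    Funnel counts are survivors after each stage and are monotone
    non-increasing.
    """
    candidates = [
        t for t in assembled if t.annotation_status == UNANNOTATED
    ]
    known = reference.subset([CODING, ANNOTATED_LNCRNA])
    lengths = {t.transcript_id: t.length for t in assembled}
    fpkm = counts.compute_fpkm(lengths)

    decisions: Dict[str, FilterDecision] = {}
    funnel: Dict[str, int] = {"unannotated": len(candidates)}
    alive = list(candidates)

    stage_fns = [
        (STAGE_LENGTH_FPKM, lambda cs: filter_length_fpkm(cs, fpkm, thr)),
        (STAGE_OVERLAP, lambda cs: filter_known_overlap(cs, known, thr)),
        (STAGE_DISTANCE, lambda cs: filter_single_exon_distance(cs, known, thr)),
    ]
    for stage, fn in stage_fns:
        reasons_by_id = fn(alive)
        survivors = []
        for t in alive:
            reasons = reasons_by_id[t.transcript_id]
            if reasons:
                decisions[t.transcript_id] = FilterDecision(
                    transcript_id=t.transcript_id,
                    stage_reached=stage,
                    reasons=reasons,
                )
            else:
                survivors.append(t)
        alive = survivors
        funnel[stage] = len(alive)

    novel = []
    for t in alive:
        score = scorer(t)
        if score < thr.coding_score_max:
            novel.append(t)
            decisions[t.transcript_id] = FilterDecision(
                transcript_id=t.transcript_id, stage_reached=STAGE_PASSED
            )
        else:
            decisions[t.transcript_id] = FilterDecision(
                transcript_id=t.transcript_id,
                stage_reached=STAGE_CODING,
                reasons=[REASON_CODING],
            )
    funnel[STAGE_CODING] = len(novel)
    funnel[STAGE_PASSED] = len(novel)

    ordered = [decisions[t.transcript_id] for t in candidates]
    return novel, ordered, funnel


def decisions_to_frame(decisions: Iterable[FilterDecision]) -> pd.DataFrame:
    """Tabular audit trail (transcript_id, stage_reached, reasons, passed)."""
    rows = [
        {
            "transcript_id": d.transcript_id,
            "stage_reached": d.stage_reached,
            "reasons": ";".join(d.reasons),
            "passed": d.passed,
        }
        for d in decisions
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "stage_reached", "reasons", "passed"]
    )
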