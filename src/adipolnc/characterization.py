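"""Comparative characterization of transcript classes.

Novel lncRNAs are compared against annotated lncRNAs and protein-coding
genes on transcript length, expression (max-over-samples FPKM), coding
potential, and exon/intron conservation, mirroring the classic lncRNA
QC panel: lncRNAs should come out shorter, lower-expressed, lower-scoring
and less conserved than coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .coding_potential import CodingPotentialResult
from .expression import ExpressionMatrix
from .models import GenomeAnnotation, TranscriptModel

PathLike = Union[str, Path]

NOVEL_LNCRNA = "novel_lncRNA"

FEATURES = ("length", "fpkm_max", "coding_score", "exon_conservation", "intron_conservation")


class ConservationError(KeyError):
    pass


class ConservationTrack:
    """Per-base conservation scores from a 4-column interval TSV.

    Input rows are (chrom, start, end, score) with 0-based half-open
    intervals, phastCons-like scores.  Bases not covered by any interval
    have no score and are ignored by the means.
    """

    def __init__(self, intervals: Mapping[str, Sequence[Tuple[int, int, float]]]):
        self._arrays: Dict[str, np.ndarray] = {}
        for chrom, rows in intervals.items():
            if not rows:
                continue
            size = max(end for _, end, _ in rows)
            arr = np.full(size, np.nan)
            for start, end, score in rows:
                arr[start:end] = score
            self._arrays[chrom] = arr

    @classmethod
    def from_tsv(cls, path: PathLike) -> "ConservationTrack":
        table = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "score"],
            comment="#",
        )
        grouped: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, score in table.itertuples(index=False):
            grouped.setdefault(str(chrom), []).append((int(start), int(end), float(score)))
        return cls(grouped)

    def chromosomes(self) -> List[str]:
        return sorted(self._arrays)

    def mean_over(
        self, chrom: str, intervals: Iterable[Tuple[int, int]]
    ) -> float:
        """Mean score over the union of bases in ``intervals``; NaN when no
        base is covered by the track."""
        if chrom not in self._arrays:
            raise ConservationError(
                f"conservation track has no chromosome {chrom!r} "
                f"(has {self.chromosomes()})"
            )
        arr = self._arrays[chrom]
        values = []
        for start, end in intervals:
            clipped = arr[start:min(end, len(arr))]
            values.append(clipped[np.isfinite(clipped)])
        if not values:
            return float("nan")
        stacked = np.concatenate(values)
        return float(stacked.mean()) if stacked.size else float("nan")


@dataclass
class ClassSummary:
    """Per-class feature vectors for one transcript class."""

    label: str
    lengths: List[int] = field(default_factory=list)
    fpkm_max: List[float] = field(default_factory=list)
    coding_scores: List[float] = field(default_factory=list)
    exon_conservation: List[float] = field(default_factory=list)
    intron_conservation: List[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.lengths)

    def feature(self, name: str) -> List[float]:
        return {
            "length": self.lengths,
            "fpkm_max": self.fpkm_max,
            "coding_score": self.coding_scores,
            "exon_conservation": self.exon_conservation,
            "intron_conservation": self.intron_conservation,
        }[name]


def summarize_class(
    label: str,
    transcripts: Sequence[TranscriptModel],
    fpkm_max: Mapping[str, float],
    coding_scores: Mapping[str, float],
    conservation: Optional[ConservationTrack] = None,
) -> ClassSummary:
    """Collect the characterization features for one transcript class.

    Exon conservation is the track mean over the transcript's exonic
    bases; intron conservation over the gaps between consecutive exons.
    Single-exon transcripts contribute no intron value.
    """
    summary = ClassSummary(label=label)
    for t in transcripts:
        tid = t.transcript_id
        summary.lengths.append(t.length)
        summary.fpkm_max.append(float(fpkm_max[tid]))
        if tid in coding_scores:
            summary.coding_scores.append(float(coding_scores[tid]))
        if conservation is not None:
            exon_mean = conservation.mean_over(
                t.chrom, [(e.start, e.end) for e in t.exons]
            )
            if np.isfinite(exon_mean):
                summary.exon_conservation.append(exon_mean)
            introns = t.introns()
            if introns:
                intron_mean = conservation.mean_over(t.chrom, introns)
                if np.isfinite(intron_mean):
                    summary.intron_conservation.append(intron_mean)
    return summary


def empirical_cdf(values: Sequence[float]) -> ECDF:
    """Right-continuous empirical CDF (0 below the min, 1 at the max)."""
    values = list(values)
    if not values:
        raise ValueError("empirical_cdf needs at least one value")
    return ECDF(values)


def class_comparison_report(
    summaries: Sequence[ClassSummary],
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Per-class medians plus pairwise two-sided rank-sum tests per feature.

    Returns a long-format table with one row per (feature, class) for
    medians and one per (feature, class_a, class_b) for tests.  Classes
    with fewer than ``min_class_size`` transcripts are summarized but not
    tested.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two classes to compare")
    rows = []
    for feat in FEATURES:
        for s in summaries:
            vals = s.feature(feat)
            rows.append(
                {
                    "feature": feat,
                    "class_a": s.label,
                    "class_b": "",
                    "kind": "median",
                    "value": float(np.median(vals)) if vals else float("nan"),
                    "n": len(vals),
                }
            )
        for i, a in enumerate(summaries):
            for b in summaries[i + 1 :]:
                va, vb = a.feature(feat), b.feature(feat)
                if len(va) < min_class_size or len(vb) < min_class_size:
                    continue
                stat, p = stats.ranksums(va, vb)
                rows.append(
                    {
                        "feature": feat,
                        "class_a": a.label,
                        "class_b": b.label,
                        "kind": "ranksum_p",
                        "value": float(p),
                        "n": len(va) + len(vb),
                    }
                )
    return pd.DataFrame(rows)


def plot_class_panels(
    summaries: Sequence[ClassSummary],
    out_prefix: PathLike,
    fpkm_floor: float = 1e-3,
) -> List[Path]:
    """Density/ECDF panels per feature (length, expression, coding
    potential, conservation), one file per feature."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    written = []
    panels = [
        ("length", "Transcript length (nt)", np.log10, "log10 length"),
        ("fpkm_max", "Max FPKM", lambda v: np.log10(np.asarray(v) + fpkm_floor), "log10(FPKM+1e-3)"),
        ("coding_score", "Coding-potential score", None, "score"),
        ("exon_conservation", "Exon conservation", None, "mean score"),
        ("intron_conservation", "Intron conservation", None, "mean score"),
    ]
    for feat, title, transform, xlabel in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        plotted = False
        for s in summaries:
            vals = np.asarray(s.feature(feat), dtype=float)
            if vals.size == 0:
                continue
            x = transform(vals) if transform else vals
            x = np.sort(x)
            ax.step(x, np.arange(1, x.size + 1) / x.size, where="post", label=s.label)
            plotted = True
        if not plotted:
            plt.close(fig)
            continue
        ax.set_title(title)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("Cumulative fraction")
        ax.legend(fontsize=8)
        path = out_prefix.parent / f"{out_prefix.name}_{feat}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
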