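"""Trainable coding-potential scorer for transcript classification.

The scorer combines four classic sequence features — longest-ORF length,
ORF coverage, the Fickett TESTCODE statistic, and in-frame hexamer usage
bias — through a logistic regression fitted on coding vs noncoding
training sequences.  The combined score is the logistic log-odds, so

    score < 0  ⇔  P(coding) < 0.5  ⇔  transcript called noncoding.

The strict-inequality decision rule (score exactly 0 is NOT noncoding)
is applied everywhere.  External scorers exposing the same signed-score
contract can be consensus-combined with :func:`consensus_noncoding`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# ---------------------------------------------------------------------------
# Fickett TESTCODE lookup tables (Fickett 1982, Nucleic Acids Res. 10:5303).
# Probability-of-coding values indexed by parameter thresholds, plus the
# per-base weights; embedded verbatim as published.
# ---------------------------------------------------------------------------

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_THRESHOLDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.73, 0.41, 0.41, 0.73, 0.70, 0.62],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_THRESHOLDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0, 0.0]

_BASES = "ACGT"
ALL_HEXAMERS = tuple(
    "".join(p) for p in itertools.product(_BASES, repeat=6)
)  # 4096 hexamers in lexicographic order
_HEXAMER_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}

FEATURE_NAMES = ("log1p_orf_length", "orf_coverage", "fickett", "hexamer")


class TrainingError(ValueError):
    """Raised when classifier/table training inputs are unusable."""


class UntrainedModelError(RuntimeError):
    """Raised when scoring is attempted before the model is fitted."""


@dataclass(frozen=True)
class OrfFeatures:
    """Longest open reading frame of a transcript (forward frames only)."""

    orf_length: int
    orf_coverage: float
    orf_start: int = -1  # 0-based start of the longest ORF; -1 when none

    def __post_init__(self) -> None:
        if self.orf_length % 3 != 0:
            raise ValueError("orf_length must be a multiple of 3")
        if not 0.0 <= self.orf_coverage <= 1.0:
            raise ValueError("orf_coverage outside [0, 1]")


@dataclass(frozen=True)
class CodingPotentialResult:
    transcript_id: str
    fickett: float
    hexamer: float
    orf: OrfFeatures
    score: float

    @property
    def is_noncoding(self) -> bool:
        return self.score < 0


def find_longest_orf(seq: str) -> OrfFeatures:
    """Longest ATG→stop ORF over the three forward frames, stop included.

    Returns zero-length features when no complete ORF exists.
    """
    seq = seq.upper()
    n = len(seq)
    best_len, best_start = 0, -1
    for frame in range(3):
        open_start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if open_start is None:
                if codon == START_CODON:
                    open_start = i
            elif codon in STOP_CODONS:
                orf_len = i + 3 - open_start
                if orf_len > best_len:
                    best_len, best_start = orf_len, open_start
                open_start = None
    coverage = best_len / n if n else 0.0
    return OrfFeatures(orf_length=best_len, orf_coverage=coverage, orf_start=best_start)


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett's TESTCODE statistic.

    Combines, per base, a position parameter (asymmetry of the base's
    counts across the three codon positions, max/(min+1)) and a content
    parameter (base fraction), each mapped through the published lookup
    tables and weighted.  Deterministic, position-sensitive.
    """
    seq = seq.upper()
    if len(seq) < 2:
        seq = seq + "N" * (2 - len(seq))
    score = 0.0
    total = len(seq)
    for base in _BASES:
        counts = [
            sum(1 for i in range(pos, total, 3) if seq[i] == base)
            for pos in range(3)
        ]
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / total
        score += (
            _lookup(position_value, _POSITION_THRESHOLDS, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content_value, _CONTENT_THRESHOLDS, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


def fickett_position_parameters(seq: str) -> Dict[str, float]:
    """The four raw position parameters max/(min+1); exposed for testing."""
    seq = seq.upper()
    out = {}
    for base in _BASES:
        counts = [
            sum(1 for i in range(pos, len(seq), 3) if seq[i] == base)
            for pos in range(3)
        ]
        out[base] = max(counts) / (min(counts) + 1)
    return out


@dataclass(frozen=True)
class HexamerTable:
    """Per-hexamer log-odds log(f_coding / f_noncoding), pseudocounted."""

    log_odds: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.log_odds) != 4096:
            raise ValueError("hexamer table must have 4096 entries")
        if not all(math.isfinite(v) for v in self.log_odds):
            raise ValueError("hexamer table entries must be finite")

    def __getitem__(self, hexamer: str) -> float:
        return self.log_odds[_HEXAMER_INDEX[hexamer]]

    def mean_in_frame(self, seq: str, start: int, length: int) -> float:
        """Mean log-odds over in-frame hexamer positions of seq[start:start+length].

        Hexamers containing N (or any non-ACGT base) are skipped.  Returns
        0.0 when no scorable hexamer exists.
        """
        values = []
        end = start + length
        for i in range(start, end - 5, 3):
            h = seq[i : i + 6]
            idx = _HEXAMER_INDEX.get(h)
            if idx is not None:
                values.append(self.log_odds[idx])
        return float(np.mean(values)) if values else 0.0


def _hexamer_counts(seqs: Iterable[str], step: int = 3) -> np.ndarray:
    counts = np.zeros(4096, dtype=float)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            idx = _HEXAMER_INDEX.get(seq[i : i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


def train_hexamer_table(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Hexamer usage log-odds from coding vs noncoding training corpora.

    Entry(h) = log( (f_cod(h)+ε) / (f_non(h)+ε) ) where f are in-frame
    hexamer frequencies and ε = ψ/4096 is the pseudocount spread over the
    hexamer alphabet.  Applying the pseudocount on the frequency scale
    makes the table invariant to corpus duplication; identical corpora
    give an all-zero table and swapping corpora negates every entry.
    """
    if not coding_seqs or not noncoding_seqs:
        raise TrainingError("both training corpora must be non-empty")
    if pseudocount <= 0:
        raise TrainingError("pseudocount must be positive")
    eps = pseudocount / 4096.0
    c_cod = _hexamer_counts(coding_seqs)
    c_non = _hexamer_counts(noncoding_seqs)
    f_cod = c_cod / max(c_cod.sum(), 1.0) + eps
    f_non = c_non / max(c_non.sum(), 1.0) + eps
    return HexamerTable(log_odds=tuple(np.log(f_cod / f_non)))


def feature_vector(seq: str, table: HexamerTable) -> np.ndarray:
    """(log1p(orf_length), orf_coverage, fickett, hexamer) for one sequence."""
    orf = find_longest_orf(seq)
    hexamer = (
        table.mean_in_frame(seq.upper(), orf.orf_start, orf.orf_length)
        if orf.orf_length > 0
        else 0.0
    )
    return np.array(
        [math.log1p(orf.orf_length), orf.orf_coverage, fickett_score(seq), hexamer]
    )


def train_classifier(
    features: np.ndarray, labels: np.ndarray, ridge_alpha: float = 1.0
) -> Tuple[float, np.ndarray]:
    """Fit logistic coefficients (intercept, betas) by maximum likelihood.

    Falls back to a ridge-penalized fit when the likelihood does not have
    a finite maximizer (perfect separation).  Deterministic given data.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2:
        raise TrainingError("features must be a 2-D array")
    if not np.isfinite(X).all():
        raise TrainingError("features must be finite")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise TrainingError("labels must contain both classes (0 and 1)")

    design = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if not np.isfinite(params).all() or np.abs(params).max() > 1e3 or not fit.mle_retvals.get("converged", False):
            raise np.linalg.LinAlgError("non-finite or runaway MLE")
    except Exception:
        # perfect separation (or near-): ridge-penalized logistic fit
        clf = LogisticRegression(
            C=1.0 / ridge_alpha, solver="lbfgs", max_iter=1000
        )
        clf.fit(X, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return float(params[0]), params[1:].copy()


def score_transcript(
    transcript_id: str,
    seq: str,
    table: HexamerTable,
    intercept: float,
    coef: np.ndarray,
) -> CodingPotentialResult:
    """Signed coding-potential score (logistic log-odds) for one transcript."""
    if table is None or coef is None:
        raise UntrainedModelError("scorer has no trained hexamer table/weights")
    seq = seq.upper()
    orf = find_longest_orf(seq)
    hexamer = (
        table.mean_in_frame(seq, orf.orf_start, orf.orf_length)
        if orf.orf_length > 0
        else 0.0
    )
    fickett = fickett_score(seq)
    x = np.array([math.log1p(orf.orf_length), orf.orf_coverage, fickett, hexamer])
    score = float(intercept + x @ np.asarray(coef, dtype=float))
    return CodingPotentialResult(
        transcript_id=transcript_id,
        fickett=fickett,
        hexamer=hexamer,
        orf=orf,
        score=score,
    )


class CodingPotentialScorer:
    """Convenience wrapper bundling hexamer table + logistic weights.

    Fit on labeled coding/noncoding sequences, then call
    :meth:`score` per transcript; serializable to JSON.
    """

    def __init__(
        self,
        table: Optional[HexamerTable] = None,
        intercept: Optional[float] = None,
        coef: Optional[np.ndarray] = None,
        pseudocount: float = 1.0,
    ) -> None:
        self.table = table
        self.intercept = intercept
        self.coef = coef
        self.pseudocount = pseudocount

    @property
    def is_fitted(self) -> bool:
        return (
            self.table is not None
            and self.intercept is not None
            and self.coef is not None
        )

    def fit(
        self, coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]
    ) -> "CodingPotentialScorer":
        self.table = train_hexamer_table(
            coding_seqs, noncoding_seqs, pseudocount=self.pseudocount
        )
        X = np.vstack(
            [feature_vector(s, self.table) for s in coding_seqs]
            + [feature_vector(s, self.table) for s in noncoding_seqs]
        )
        y = np.concatenate(
            [np.ones(len(coding_seqs)), np.zeros(len(noncoding_seqs))]
        )
        self.intercept, self.coef = train_classifier(X, y)
        return self

    def score(self, transcript_id: str, seq: str) -> CodingPotentialResult:
        if not self.is_fitted:
            raise UntrainedModelError(
                "CodingPotentialScorer must be fitted before scoring"
            )
        return score_transcript(
            transcript_id, seq, self.table, self.intercept, self.coef
        )

    def score_many(
        self, sequences: Mapping[str, str]
    ) -> Dict[str, CodingPotentialResult]:
        return {tid: self.score(tid, s) for tid, s in sequences.items()}

    def to_json(self, path: Union[str, Path]) -> None:
        if not self.is_fitted:
            raise UntrainedModelError("cannot serialize an unfitted scorer")
        payload = {
            "intercept": self.intercept,
            "coef": list(map(float, self.coef)),
            "feature_names": list(FEATURE_NAMES),
            "pseudocount": self.pseudocount,
            "hexamer_log_odds": list(map(float, self.table.log_odds)),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CodingPotentialScorer":
        payload = json.loads(Path(path).read_text())
        return cls(
            table=HexamerTable(log_odds=tuple(payload["hexamer_log_odds"])),
            intercept=float(payload["intercept"]),
            coef=np.array(payload["coef"], dtype=float),
            pseudocount=float(payload.get("pseudocount", 1.0)),
        )


def consensus_noncoding(
    results: Iterable[CodingPotentialResult],
) -> bool:
    """AND-combine noncoding verdicts from multiple scorers (CPAT/COME-style
    dual-tool consensus reduces to this when external scores are supplied)."""
    results = list(results)
    if not results:
        raise ValueError("no scorer results to combine")
    return all(r.is_noncoding for r in results)
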