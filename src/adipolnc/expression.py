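"""Expression matrix container: counts, sample groups, and FPKM."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Per-transcript counts across named samples grouped by cell type.

    ``counts`` is features × samples.  ``sample_groups`` maps each group
    (cell type) to its sample names; every sample must belong to exactly
    one group.  FPKM is derived lazily from counts and transcript lengths
    unless a precomputed FPKM table is supplied.
    """

    counts: pd.DataFrame
    sample_groups: Dict[str, List[str]]
    fpkm: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        assigned = [s for group in self.sample_groups.values() for s in group]
        if len(assigned) != len(set(assigned)):
            raise ExpressionError("a sample appears in more than one group")
        missing = set(assigned) - set(self.counts.columns)
        if missing:
            raise ExpressionError(f"grouped samples missing from counts: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ExpressionError("counts must be non-negative")

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> List[str]:
        return list(self.counts.index)

    def group_of(self, sample: str) -> str:
        for g, members in self.sample_groups.items():
            if sample in members:
                return g
        raise KeyError(sample)

    def compute_fpkm(self, lengths: Mapping[str, int]) -> pd.DataFrame:
        """FPKM[t, s] = count / ((length_kb) * (column_total / 1e6)).

        The per-sample library size is the column sum of counts.  A
        precomputed FPKM table, when present, is returned verbatim.
        """
        if self.fpkm is not None:
            return self.fpkm
        totals = self.counts.sum(axis=0)
        zero = totals[totals <= 0]
        if len(zero):
            raise ExpressionError(
                f"zero library size for sample(s): {', '.join(zero.index)}"
            )
        length_kb = pd.Series(
            {t: lengths[t] / 1000.0 for t in self.counts.index}, dtype=float
        )
        if (length_kb <= 0).any():
            raise ExpressionError("transcript lengths must be >= 1 nt")
        fpkm = self.counts.div(totals / 1e6, axis=1).div(length_kb, axis=0)
        self.fpkm = fpkm
        return fpkm

    def max_fpkm(self, lengths: Mapping[str, int]) -> pd.Series:
        """Per-transcript max-over-samples FPKM."""
        return self.compute_fpkm(lengths).max(axis=1)

    @classmethod
    def from_tsv(
        cls,
        path: PathLike,
        sample_groups: Optional[Dict[str, List[str]]] = None,
        is_fpkm: bool = False,
    ) -> "ExpressionMatrix":
        table = pd.read_csv(path, sep="\t", index_col=0)
        if sample_groups is None:
            # infer groups from "Group-replicate" sample names
            sample_groups = {}
            for s in table.columns:
                sample_groups.setdefault(s.rsplit("-", 1)[0], []).append(s)
        if is_fpkm:
            return cls(
                counts=table, sample_groups=sample_groups, fpkm=table
            )
        return cls(counts=table, sample_groups=sample_groups)

    def to_tsv(self, path: PathLike) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")
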