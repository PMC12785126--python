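"""Cross-contrast integration: Venn intersection of DEG sets, up/down
tallies, cis target assignment by genomic position, and hypergeometric
term enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .models import CODING, GenomeAnnotation, TranscriptModel

DEFAULT_CIS_WINDOW = 100_000  # bp

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
OVERLAPPING = "overlapping"
SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class CisTargetCall:
    """A lncRNA's nearest coding gene and their relative geometry.

    ``relative_position`` is expressed in the target gene's orientation:
    downstream means past the gene's 3' end.  ``relative_strand`` is
    sense when lncRNA and gene share a strand.
    """

    lncrna_id: str
    target_gene_id: str
    relative_position: str
    relative_strand: str
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.relative_position == OVERLAPPING and self.distance != 0:
            raise ValueError("overlapping call must have distance 0")


@dataclass(frozen=True)
class VennResult:
    """Exclusive region memberships of a named family of sets."""

    set_names: Tuple[str, ...]
    regions: Dict[FrozenSet[str], FrozenSet[str]]

    @property
    def common(self) -> FrozenSet[str]:
        return self.regions.get(frozenset(self.set_names), frozenset())

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())

    def region_sizes(self) -> Dict[FrozenSet[str], int]:
        return {k: len(v) for k, v in self.regions.items()}


def intersect_contrasts(deg_sets: Mapping[str, Set[str]]) -> VennResult:
    """Exclusive Venn regions of >= 2 named feature sets.

    Each feature of the union lands in exactly one region — the one keyed
    by the exact combination of sets containing it — so region sizes sum
    to the union size.  ``common`` is the all-sets intersection.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two sets to intersect")
    names = tuple(deg_sets)
    membership: Dict[FrozenSet[str], Set[str]] = {}
    for feature in set().union(*deg_sets.values()):
        key = frozenset(n for n in names if feature in deg_sets[n])
        membership.setdefault(key, set()).add(feature)
    regions = {k: frozenset(v) for k, v in membership.items()}
    return VennResult(set_names=names, regions=regions)


def updown_table(
    results_per_contrast: Mapping[str, pd.DataFrame],
    lncrna_ids: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Per-contrast (n_up, n_down) tallies, overall and lncRNA-only.

    n_up + n_down equals the number of significant features per contrast
    and class.
    """
    rows = []
    for name, res in results_per_contrast.items():
        sig = res[res["significant"].fillna(False).astype(bool)]
        row = {
            "contrast": name,
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
        }
        if lncrna_ids is not None:
            lnc = sig[sig.index.isin(lncrna_ids)]
            row["n_up_lncrna"] = int((lnc["direction"] == "up").sum())
            row["n_down_lncrna"] = int((lnc["direction"] == "down").sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("contrast")


def _gene_spans(
    coding: GenomeAnnotation,
) -> Dict[str, List[Tuple[str, int, int, str, str]]]:
    """Per-chromosome gene loci (gene_id, start, end, strand) from the
    union of each gene's transcript spans."""
    genes: Dict[str, List[int]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    for t in coding:
        if t.annotation_status != CODING:
            continue
        s, e = t.span
        if t.gene_id in genes:
            genes[t.gene_id][0] = min(genes[t.gene_id][0], s)
            genes[t.gene_id][1] = max(genes[t.gene_id][1], e)
        else:
            genes[t.gene_id] = [s, e]
            meta[t.gene_id] = (t.chrom, t.strand)
    by_chrom: Dict[str, List[Tuple[str, int, int, str, str]]] = {}
    for gid, (s, e) in genes.items():
        chrom, strand = meta[gid]
        by_chrom.setdefault(chrom, []).append((gid, s, e, strand, chrom))
    return by_chrom


def assign_cis_target(
    lncrna: TranscriptModel,
    coding: GenomeAnnotation,
    max_distance: int = DEFAULT_CIS_WINDOW,
) -> Optional[CisTargetCall]:
    """Nearest coding gene within ``max_distance`` of the lncRNA locus.

    Distance is the boundary gap between the lncRNA span and the gene
    span (0 when they overlap).  Ties on distance break toward the
    lexicographically smaller gene_id.  Returns None when no coding gene
    lies in range.
    """
    spans = _gene_spans(coding).get(lncrna.chrom, [])
    l_start, l_end = lncrna.span
    best: Optional[Tuple[int, str, Tuple[int, int, str]]] = None
    for gid, g_start, g_end, g_strand, _ in spans:
        if l_end <= g_start:
            gap = g_start - l_end
        elif g_end <= l_start:
            gap = l_start - g_end
        else:
            gap = 0
        if gap > max_distance:
            continue
        key = (gap, gid)
        if best is None or key < (best[0], best[1]):
            best = (gap, gid, (g_start, g_end, g_strand))
    if best is None:
        return None
    gap, gid, (g_start, g_end, g_strand) = best
    if gap == 0:
        position = OVERLAPPING
    else:
        lnc_is_right = l_start >= g_end
        # express position in the gene's orientation: for a + gene, right
        # of the gene is downstream; for a - gene, left is downstream
        if g_strand == "+":
            position = DOWNSTREAM if lnc_is_right else UPSTREAM
        else:
            position = UPSTREAM if lnc_is_right else DOWNSTREAM
    strand_rel = SENSE if lncrna.strand == g_strand else ANTISENSE
    return CisTargetCall(
        lncrna_id=lncrna.transcript_id,
        target_gene_id=gid,
        relative_position=position,
        relative_strand=strand_rel,
        distance=gap,
    )


def assign_cis_targets(
    lncrnas: Iterable[TranscriptModel],
    coding: GenomeAnnotation,
    max_distance: int = DEFAULT_CIS_WINDOW,
) -> pd.DataFrame:
    calls = []
    for t in lncrnas:
        call = assign_cis_target(t, coding, max_distance=max_distance)
        if call is not None:
            calls.append(
                {
                    "lncrna_id": call.lncrna_id,
                    "target_gene_id": call.target_gene_id,
                    "relative_position": call.relative_position,
                    "relative_strand": call.relative_strand,
                    "distance": call.distance,
                }
            )
    return pd.DataFrame(
        calls,
        columns=[
            "lncrna_id",
            "target_gene_id",
            "relative_position",
            "relative_strand",
            "distance",
        ],
    )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric instance k={k} N={N} K={K} n={n}")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich(
    query: Set[str],
    term_map: Mapping[str, Set[str]],
    universe: Set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation test per term.

    For a term covering K of N universe genes with k hits in a query of
    size n, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Terms with no hit
    are skipped; BH adjustment runs across the tested terms.

    ``term_map`` maps term_id -> gene set.
    """
    offenders = query - universe
    if offenders:
        raise ValueError(
            f"query genes outside the universe: {sorted(offenders)[:5]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(term_map):
        members = term_map[term_id] & universe
        K = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append(
            {
                "term_id": term_id,
                "term_size": K,
                "hits": k,
                "query_size": n,
                "universe_size": N,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_size", "hits", "query_size", "universe_size", "p"],
    )
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
    else:
        result["padj"] = pd.Series(dtype=float)
    return result.sort_values("p").reset_index(drop=True)


def read_term_map(path) -> Dict[str, Set[str]]:
    """TSV (gene_id, term_id[, term_name]) -> {term_id: genes}."""
    table = pd.read_csv(path, sep="\t")
    out: Dict[str, Set[str]] = {}
    for gene, term in zip(table.iloc[:, 0], table.iloc[:, 1]):
        out.setdefault(str(term), set()).add(str(gene))
    return out
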