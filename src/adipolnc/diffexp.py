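"""Negative-binomial differential expression between adipocyte types.

A deliberately simple NB pipeline in the DESeq2 mold: median-of-ratios
size factors, per-feature method-of-moments dispersion moderated toward
a Cox–Reid-adjusted common dispersion, a Wald test on the log2 fold
change of normalized group means, and Benjamini–Hochberg FDR control.  Significance uses the strict rule padj < 0.05 AND
|log2FC| > 1.  This is not a numeric clone of DESeq2 (no Cox–Reid
dispersion likelihood, no fold-change shrinkage), so counts called on
real data will differ from DESeq2's; the statistical contracts
(normalization equivariance, type-I calibration, BH correctness) are
what the module guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

DEFAULT_PADJ_MAX = 0.05
DEFAULT_LFC_MIN = 1.0
DEFAULT_COUNT_OFFSET = 0.5  # c0, in normalized-count units


class DiffExpError(ValueError):
    pass


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; log2 fold changes are group_a over group_b."""

    name: str
    group_a: Tuple[str, ...]
    group_b: Tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise DiffExpError(f"{self.name}: both groups must be non-empty")
        if a & b:
            raise DiffExpError(f"{self.name}: groups share samples {sorted(a & b)}")

    def swapped(self) -> "Contrast":
        return Contrast(
            name=f"{self.name}_swapped",
            group_a=self.group_b,
            group_b=self.group_a,
        )


def size_factors(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios normalization (the DESeq estimator).

    s_j = median over reference features of count[i, j] / geomean_i, where
    reference features have all-positive counts.  With
    ``pseudo_reference=True``, features positive in at least one sample are
    used with zeros ignored in the geometric mean — the fallback when no
    feature is positive everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        if not pseudo_reference:
            raise DiffExpError(
                "no feature has positive counts in every sample; re-run with "
                "pseudo_reference=True"
            )
        logs = np.full(mat.shape, np.nan)
        np.log(mat, out=logs, where=mat > 0)
        log_geomean = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_geomean)
    else:
        logs = np.log(mat[all_positive])
        log_geomean = logs.mean(axis=1)
        usable = np.ones(log_geomean.shape[0], dtype=bool)
        mat = mat[all_positive]
    with np.errstate(divide="ignore"):
        log_ratios = np.log(mat[usable]) - log_geomean[usable, None]
    s = np.exp(np.nanmedian(log_ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def estimate_dispersion(
    norm_counts: pd.DataFrame,
    groups: Sequence[Sequence[str]],
) -> pd.Series:
    """Per-feature NB dispersion by the method of moments.

    Within-group variances are pooled and α = max(0, (var − mean) / mean²)
    on normalized counts.  Features with zero mean get NaN (skipped by the
    Wald test).
    """
    mat_groups = [norm_counts[list(g)].to_numpy(dtype=float) for g in groups]
    means = np.hstack([g.mean(axis=1, keepdims=True) for g in mat_groups])
    overall_mean = np.hstack(mat_groups).mean(axis=1)
    # pooled within-group variance with Bessel correction
    ss = np.zeros(norm_counts.shape[0])
    df = 0
    for g in mat_groups:
        ss += ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += g.shape[1] - 1
    if df <= 0:
        raise DiffExpError("dispersion estimation needs replicates")
    pooled_var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            overall_mean > 0,
            np.maximum(0.0, (pooled_var - overall_mean) / overall_mean**2),
            np.nan,
        )
    return pd.Series(alpha, index=norm_counts.index, name="dispersion")


def common_dispersion(
    counts: pd.DataFrame,
    s: pd.Series,
    groups: Sequence[Sequence[str]],
    grid: Optional[np.ndarray] = None,
) -> float:
    """Single dispersion shared by all features, by profile likelihood.

    Maximizes the summed NB log-likelihood over a log-spaced α grid with
    group means as plug-in nuisance parameters and a Cox–Reid adjustment
    (0.5·log Σ w per group) to de-bias the plug-in.  This anchors the
    per-feature moment estimates, which are extremely noisy at the 2–3
    replicates typical of these designs.
    """
    K = counts.to_numpy(dtype=float)
    sv = s[counts.columns].to_numpy(dtype=float)
    cols = list(counts.columns)
    gidx = [[cols.index(x) for x in g] for g in groups]
    norm = K / sv
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(4.0), 60))
    best, best_ll = float(grid[0]), -np.inf
    for a in grid:
        r = 1.0 / a
        ll = 0.0
        for gi in gidx:
            Kg = K[:, gi]
            q = norm[:, gi].mean(axis=1)
            mu = np.maximum(q[:, None] * sv[gi][None, :], 1e-8)
            ll_mat = (
                gammaln(Kg + r)
                - gammaln(r)
                - gammaln(Kg + 1)
                + r * np.log(r / (r + mu))
                + Kg * np.log(mu / (r + mu))
            )
            w = mu / (1.0 + a * mu)
            ll += float((ll_mat.sum(axis=1) - 0.5 * np.log(w.sum(axis=1))).sum())
        if ll > best_ll:
            best_ll, best = ll, float(a)
    return best


def moderated_dispersion(
    counts: pd.DataFrame,
    s: pd.Series,
    groups: Sequence[Sequence[str]],
    prior_df: float = 20.0,
) -> pd.Series:
    """Per-feature dispersions shrunk toward the common value.

    α_i = (d0·α_common + d·α_i^MoM) / (d0 + d) with d the residual
    degrees of freedom.  The prior dominates at low replication, which
    is what keeps the Wald test near its nominal size there.
    """
    norm = counts.div(s[counts.columns], axis=1)
    per_feature = estimate_dispersion(norm, groups)
    a_common = common_dispersion(counts, s, groups)
    d = sum(len(g) - 1 for g in groups)
    shrunk = (prior_df * a_common + d * per_feature.fillna(a_common)) / (
        prior_df + d
    )
    return shrunk.rename("dispersion")


def wald_test(
    counts: pd.DataFrame,
    s: pd.Series,
    alpha: pd.Series,
    contrast: Contrast,
    c0: float = DEFAULT_COUNT_OFFSET,
) -> pd.DataFrame:
    """Wald test of log2(mean_a / mean_b) on normalized counts.

    log2fc = log2(mean_a + c0) − log2(mean_b + c0); the standard error
    comes from the NB variance of each sample's normalized count via the
    delta method; p-values are two-sided normal.  Features with zero
    counts in both groups get log2fc 0, p 1.
    """
    a_cols, b_cols = list(contrast.group_a), list(contrast.group_b)
    norm = counts.div(s, axis=1)
    mean_a = norm[a_cols].mean(axis=1)
    mean_b = norm[b_cols].mean(axis=1)
    base_mean = norm[a_cols + b_cols].mean(axis=1)

    log2fc = np.log2(mean_a + c0) - np.log2(mean_b + c0)

    al = alpha.reindex(counts.index).fillna(0.0).to_numpy()

    def group_mean_var(mean: pd.Series, cols: List[str]) -> np.ndarray:
        # Var(K_ij / s_j) = mu_i/s_j + alpha * mu_i^2 under NB(mu_i*s_j, alpha);
        # mu floored by c0 so zero-count groups keep a finite SE.
        mu = np.maximum(mean.to_numpy(), 0.0) + c0
        inv_s = (1.0 / s[cols]).sum()
        n = len(cols)
        return (mu * inv_s + n * al * mu**2) / n**2

    var_a = group_mean_var(mean_a, a_cols)
    var_b = group_mean_var(mean_b, b_cols)
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_a / ((mean_a.to_numpy() + c0) * ln2) ** 2
        + var_b / ((mean_b.to_numpy() + c0) * ln2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc.to_numpy() / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    both_zero = (counts[a_cols].sum(axis=1) == 0) & (
        counts[b_cols].sum(axis=1) == 0
    )
    log2fc = log2fc.where(~both_zero, 0.0)
    p = np.where(both_zero.to_numpy(), 1.0, p)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
        },
        index=counts.index,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise DiffExpError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: pd.DataFrame,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> Tuple[Set[str], Set[str]]:
    """Partition significant features into up- and down-regulated sets.

    up: padj < padj_max AND log2fc > lfc_min; down: padj < padj_max AND
    log2fc < −lfc_min (all strict).  The union is the significant set.
    """
    sig = results["padj"] < padj_max
    up = set(results.index[sig & (results["log2fc"] > lfc_min)])
    down = set(results.index[sig & (results["log2fc"] < -lfc_min)])
    return up, down


def run_contrast(
    counts: pd.DataFrame,
    contrast: Contrast,
    s: Optional[pd.Series] = None,
    alpha: Optional[pd.Series] = None,
    c0: float = DEFAULT_COUNT_OFFSET,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full per-contrast analysis: normalize, test, adjust, call.

    Features with zero counts in every sample are dropped before testing
    and excluded from the BH family size.
    """
    cols = list(contrast.group_a) + list(contrast.group_b)
    missing = set(cols) - set(counts.columns)
    if missing:
        raise DiffExpError(f"{contrast.name}: samples not in matrix: {sorted(missing)}")
    sub = counts[cols]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if s is None:
        s = size_factors(sub, pseudo_reference=pseudo_reference)
    else:
        s = s[cols]
    if alpha is None:
        alpha = moderated_dispersion(
            sub, s, [list(contrast.group_a), list(contrast.group_b)]
        )
    res = wald_test(sub, s, alpha, contrast, c0=c0)
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = (res["padj"] < padj_max) & (res["log2fc"].abs() > lfc_min)
    res["direction"] = np.select(
        [
            res["significant"] & (res["log2fc"] > lfc_min),
            res["significant"] & (res["log2fc"] < -lfc_min),
        ],
        ["up", "down"],
        default="ns",
    )
    res.index.name = "feature_id"
    return res


def de_analysis(
    matrix_counts: pd.DataFrame,
    contrasts: Iterable[Contrast],
    **kwargs,
) -> Dict[str, pd.DataFrame]:
    return {c.name: run_contrast(matrix_counts, c, **kwargs) for c in contrasts}


def contrasts_from_groups(
    sample_groups: Mapping[str, Sequence[str]],
    pairs: Sequence[Tuple[str, str]] = (
        ("White", "Brown"),
        ("Beige", "White"),
        ("Beige", "Brown"),
    ),
) -> List[Contrast]:
    """Build the three standard adipocyte contrasts from sample groups."""
    out = []
    for a, b in pairs:
        out.append(
            Contrast(
                name=f"{a}_vs_{b}",
                group_a=tuple(sample_groups[a]),
                group_b=tuple(sample_groups[b]),
            )
        )
    return out
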