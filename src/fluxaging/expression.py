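"""Count normalization, per-gene group z-scores, DEG filter, preranked GSEA.

Normalization is median-of-ratios size factoring (geometric-mean reference
over genes with all-positive counts) followed by log2 with a pseudocount —
a documented, monotone stand-in for a variance-stabilizing transform;
every downstream consumer (z-scores, percentile confidence scoring, GSEA
ranking) depends only on monotone, scale-stabilized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import GeneSetCollection
from .synthetic_data import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "normalize",
    "gene_zscores",
    "de_table",
    "select_degs",
    "preranked_gsea",
]


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale expression (genes x samples) with provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    groups: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def group_mean(self, group: str) -> pd.Series:
        cols = [s for s, g in self.groups.items() if g == group and s in self.values.columns]
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[cols].mean(axis=1)


def normalize(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Median-of-ratios size factors, then log2(count/sf + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    mat = counts.counts.astype(float)
    col_sums = mat.sum(axis=0)
    empty = list(col_sums.index[col_sums == 0])
    if empty:
        raise ValueError(f"sample(s) with all-zero counts: {empty}")
    allpos = mat.index[(mat > 0).all(axis=1)]
    if len(allpos) == 0:
        raise ValueError("no gene has positive counts in every sample; cannot size-factor")
    ref = np.exp(np.log(mat.loc[allpos]).mean(axis=1))
    size_factors = mat.loc[allpos].div(ref, axis=0).median(axis=0)
    values = np.log2(mat.div(size_factors, axis=1) + pseudocount)
    return ExpressionMatrix(
        values=values,
        size_factors=size_factors,
        groups=dict(counts.groups),
        provenance={
            "method": "median_of_ratios_log2",
            "pseudocount": pseudocount,
            "n_reference_genes": int(len(allpos)),
        },
    )


def _group_columns(expr: ExpressionMatrix, group: str) -> list:
    cols = [s for s in expr.samples if expr.groups.get(s) == group]
    if not cols:
        raise ValueError(f"unknown or empty group label {group!r}")
    return cols


def gene_zscores(expr: ExpressionMatrix, contrast: tuple) -> pd.DataFrame:
    """Per-gene z = (mean_A - mean_B) / pooled SE for contrast (A, B).

    Pooled within-group variance with nA+nB-2 df; genes whose pooled SD is
    zero get z = 0 and ``zero_variance=True``. Antisymmetric in the
    contrast direction.
    """
    group_a, group_b = contrast
    cols_a = _group_columns(expr, group_a)
    cols_b = _group_columns(expr, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both contrast groups need >=2 samples")
    a = expr.values[cols_a].to_numpy()
    b = expr.values[cols_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    zero = se == 0
    z = np.zeros(len(mean_diff))
    z[~zero] = mean_diff[~zero] / se[~zero]
    return pd.DataFrame(
        {"z": z, "mean_diff": mean_diff, "zero_variance": zero},
        index=expr.values.index,
    )


def de_table(expr: ExpressionMatrix, contrast: tuple) -> pd.DataFrame:
    """Per-gene log2 fold change (difference of log2 means) and Welch-t p."""
    group_a, group_b = contrast
    a = expr.values[_group_columns(expr, group_a)].to_numpy()
    b = expr.values[_group_columns(expr, group_b)].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"log2fc": lfc, "pvalue": p}, index=expr.values.index)


def select_degs(table: pd.DataFrame, lfc_cut: float = 2.0, p_cut: float = 0.05) -> set:
    """Genes with |log2FC| >= lfc_cut AND p < p_cut (cutoffs as printed)."""
    lfc = table["log2fc"].to_numpy()
    p = table["pvalue"].to_numpy()
    if not np.isfinite(lfc).all():
        raise ValueError("log2fc column contains non-finite values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("pvalue column outside [0, 1]")
    keep = (np.abs(lfc) >= lfc_cut) & (p < p_cut)
    return set(table.index[keep])


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _running_es(order_scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Enrichment score: max-|deviation| of the weighted KS running sum."""
    n = len(order_scores)
    n_hit = int(hit_mask.sum())
    w = np.abs(order_scores) ** weight
    w_hit = np.where(hit_mask, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted steps
        w_hit = hit_mask.astype(float)
        denom = float(n_hit)
    steps = w_hit / denom - (~hit_mask) / float(n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranking: Mapping[str, float] | pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with gene-label permutation NES/p.

    Genes are ordered by decreasing score (ties broken by gene id for
    determinism). ES is the signed maximal deviation of the weighted
    Kolmogorov-Smirnov running sum (hit increments proportional to
    |score|**weight over the set, miss decrement 1/(N - set size)). NES
    divides ES by the mean |ES*| of same-sign gene-label permutations; the
    permutation p-value is (1 + #{|ES*| >= |ES|, same sign}) / (1 + #same
    sign). Sets smaller than ``min_size`` after intersection with the
    ranking are reported with NaN statistics and ``excluded=True``.
    """
    if isinstance(ranking, pd.Series):
        ranking = ranking.astype(float)
    else:
        ranking = pd.Series(ranking, dtype=float)
    if ranking.index.duplicated().any():
        raise ValueError("ranking contains duplicate gene ids")
    order = ranking.reset_index()
    order.columns = ["gene", "score"]
    order = order.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    genes = order["gene"].to_numpy()
    scores = order["score"].to_numpy()
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.items():
        pos = sorted(gene_pos[g] for g in set(members) if g in gene_pos)
        size = len(pos)
        if size < min_size or size >= n:
            rows.append(
                {"set": name, "size": size, "es": np.nan, "nes": np.nan,
                 "pvalue": np.nan, "excluded": True}
            )
            continue
        mask = np.zeros(n, dtype=bool)
        mask[pos] = True
        es = _running_es(scores, mask, weight)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=size, replace=False)] = True
            perm_es[b] = _running_es(scores, pmask, weight)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same_sign) == 0:
            nes = np.nan
            pval = 1.0 / (1.0 + n_perm)
        else:
            nes = es / np.mean(np.abs(same_sign))
            pval = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
        rows.append(
            {"set": name, "size": size, "es": es, "nes": nes,
             "pvalue": pval, "excluded": False}
        )
    out = pd.DataFrame(rows).set_index("set")
    if out["excluded"].all() and len(out):
        import warnings

        warnings.warn("all gene sets fall below min_size; empty enrichment result")
    return out
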