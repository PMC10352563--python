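"""Van der Waerden k-sample comparison of flux profiles and summaries.

The Van der Waerden (VdW) test replaces pooled ranks R_ij (average ranks on
ties) by normal scores A_ij = Phi^-1(R_ij / (N+1)); with s^2 the mean
squared score (N-1 denominator), the statistic T = (1/s^2) * sum_j n_j *
Abar_j^2 is asymptotically chi-square with k-1 degrees of freedom. An
exact/Monte-Carlo permutation p-value is available because the chi-square
approximation is crude at the small per-group sizes typical of bulk
RNA-seq designs.

Banding follows the flux-heatmap convention of the target analysis:
"sig" for p < 0.05, "marginal" for 0.05 <= p < 0.1, otherwise "ns"; raw
p-values are used for bands (no multiplicity correction), with a
Benjamini-Hochberg q-value column provided as a safety rail.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VdwResult",
    "vdw_test",
    "compare_flux_table",
    "row_zscores",
    "pathway_summary",
]

_EXACT_LIMIT = 20000  # enumerate permutations exactly up to this many


@dataclass
class VdwResult:
    statistic: float
    df: int
    pvalue: float
    degenerate: bool = False
    method: str = "chi2"


def _normal_scores(pooled: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(pooled, method="average")
    return stats.norm.ppf(ranks / (len(pooled) + 1.0))


def _vdw_statistic(scores: np.ndarray, sizes: Sequence[int]) -> float:
    n_total = len(scores)
    s2 = float(np.sum(scores**2)) / (n_total - 1)
    if s2 <= 0:
        return math.nan
    t = 0.0
    start = 0
    for n_j in sizes:
        mean_j = float(scores[start : start + n_j].mean())
        t += n_j * mean_j**2
        start += n_j
    return t / s2


def _group_assignments(sizes: Sequence[int]):
    """Yield index tuples assigning positions 0..N-1 to groups of the given sizes."""
    n_total = sum(sizes)

    def rec(remaining: tuple, sizes_left: Sequence[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in chosen)
            for tail in rec(rest, sizes_left[1:]):
                yield (chosen,) + tail

    yield from rec(tuple(range(n_total)), sizes)


def _n_assignments(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for n_j in sizes:
        total //= math.factorial(n_j)
    return total


def vdw_test(
    values: Sequence[Sequence[float]],
    method: str = "chi2",
    n_perm: int = 9999,
    seed: int = 0,
) -> VdwResult:
    """Van der Waerden normal-scores test across k groups of observations.

    ``method="chi2"`` uses the asymptotic chi-square reference with k-1 df;
    ``"permutation"`` enumerates all group assignments exactly when their
    number is at most 20000 and otherwise Monte-Carlo samples ``n_perm``
    label shuffles. All observations identical -> degenerate: statistic
    NaN, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in values]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = [len(g) for g in groups]
    if min(sizes) < 1:
        raise ValueError("every group must be nonempty")
    n_total = sum(sizes)
    if n_total < k + 1:
        raise ValueError("need total N >= k + 1 observations")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return VdwResult(math.nan, k - 1, 1.0, degenerate=True, method=method)

    scores = _normal_scores(pooled)
    t_obs = _vdw_statistic(scores, sizes)
    if math.isnan(t_obs):
        return VdwResult(math.nan, k - 1, 1.0, degenerate=True, method=method)

    if method == "chi2":
        p = float(stats.chi2.sf(t_obs, k - 1))
    elif method == "permutation":
        tol = 1e-9
        if _n_assignments(sizes) <= _EXACT_LIMIT:
            count = total = 0
            for assignment in _group_assignments(sizes):
                perm_scores = np.concatenate([scores[list(idx)] for idx in assignment])
                if _vdw_statistic(perm_scores, sizes) >= t_obs - tol:
                    count += 1
                total += 1
            p = count / total
        else:
            rng = np.random.default_rng(seed)
            mat = rng.permuted(np.tile(scores, (n_perm, 1)), axis=1)
            s2 = float(np.sum(scores**2)) / (n_total - 1)  # permutation-invariant
            t_perm = np.zeros(n_perm)
            start = 0
            for n_j in sizes:
                t_perm += n_j * mat[:, start : start + n_j].mean(axis=1) ** 2
                start += n_j
            t_perm /= s2
            count = int(np.sum(t_perm >= t_obs - tol))
            p = (1.0 + count) / (1.0 + n_perm)
    else:
        raise ValueError("method must be 'chi2' or 'permutation'")
    return VdwResult(float(t_obs), k - 1, p, degenerate=False, method=method)


def _band(p: float, degenerate: bool) -> str:
    if degenerate or not np.isfinite(p):
        return "ns"
    if p < 0.05:
        return "sig"
    if p < 0.1:
        return "marginal"
    return "ns"


def compare_flux_table(
    fluxes: pd.DataFrame,
    groups: Mapping[str, str],
    method: str = "chi2",
    n_perm: int = 9999,
    seed: int = 0,
    subsystems: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Row-wise VdW comparison of a reactions x samples flux table.

    Returns a table indexed by reaction with the VdW statistic, df,
    p-value, significance band, BH q-value and a degenerate flag
    (constant rows). Requires every flux column mapped to a group and at
    least two samples per group.
    """
    unmapped = [s for s in fluxes.columns if s not in groups]
    if unmapped:
        raise ValueError(f"flux sample(s) without group assignment: {unmapped}")
    labels = [groups[s] for s in fluxes.columns]
    order = list(dict.fromkeys(labels))
    cols_by_group = {g: [s for s in fluxes.columns if groups[s] == g] for g in order}
    small = [g for g, cols in cols_by_group.items() if len(cols) < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")

    rows = []
    for rid, row in fluxes.iterrows():
        vals = [row[cols_by_group[g]].to_numpy(dtype=float) for g in order]
        res = vdw_test(vals, method=method, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "reaction": rid,
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
                "degenerate": res.degenerate,
                "band": _band(res.pvalue, res.degenerate),
            }
        )
    out = pd.DataFrame(rows).set_index("reaction")
    ok = ~out["degenerate"]
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
    out["qvalue"] = q
    if subsystems is not None:
        out.insert(0, "subsystem", [subsystems.get(r, "unassigned") for r in out.index])
    return out


def row_zscores(fluxes: pd.DataFrame) -> tuple:
    """Row-wise Z-scores (x - row mean) / row SD (ddof=1).

    Returns ``(zscores, zero_sd_flags)``; zero-SD rows become all-zero and
    are flagged (they carry no contrast and are excluded from heatmaps).
    """
    mat = fluxes.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    z = (mat - mean) / sd
    z[zero, :] = 0.0
    zdf = pd.DataFrame(z, index=fluxes.index, columns=fluxes.columns)
    flags = pd.Series(zero, index=fluxes.index, name="zero_sd")
    return zdf, flags


def pathway_summary(
    result: pd.DataFrame,
    zscores: pd.DataFrame,
    subsystems: Mapping[str, str],
    groups: Mapping[str, str],
    contrast_group: str = "KO_old",
) -> pd.DataFrame:
    """Per-subsystem band tallies, per-group median Z, and direction call.

    Direction is "decreased"/"increased" when the median row-Z of the
    subsystem's significant (p < 0.05) reactions over the contrast group's
    samples is negative/positive, and "none" when the subsystem has no
    significant reactions.
    """
    group_order = list(dict.fromkeys(groups[s] for s in zscores.columns))
    if contrast_group not in group_order:
        raise ValueError(f"contrast group {contrast_group!r} has no flux samples")
    sub_of = {rid: subsystems.get(rid, "unassigned") for rid in result.index}
    rows = []
    for sub in dict.fromkeys(sub_of.values()):
        rids = [r for r, s in sub_of.items() if s == sub]
        res = result.loc[rids]
        sig = list(res.index[res["band"] == "sig"])
        rec = {
            "subsystem": sub,
            "n_reactions": len(rids),
            "n_sig": len(sig),
            "n_marginal": int((res["band"] == "marginal").sum()),
            "n_ns": int((res["band"] == "ns").sum()),
        }
        for g in group_order:
            cols = [s for s in zscores.columns if groups[s] == g]
            rec[f"median_z_{g}"] = (
                float(np.median(zscores.loc[rids, cols].to_numpy())) if rids else np.nan
            )
        if not sig:
            rec["direction"] = "none"
        else:
            cols = [s for s in zscores.columns if groups[s] == contrast_group]
            med = float(np.median(zscores.loc[sig, cols].to_numpy()))
            rec["direction"] = "decreased" if med < 0 else ("increased" if med > 0 else "none")
        rows.append(rec)
    return pd.DataFrame(rows).set_index("subsystem")
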