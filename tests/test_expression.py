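import math

import numpy as np
import pandas as pd
import pytest

from helpers import es_bruteforce
from fluxaging.expression import (
    de_table,
    gene_zscores,
    normalize,
    preranked_gsea,
    select_degs,
)
from fluxaging.model_io import GeneSetCollection
from fluxaging.synthetic_data import CountMatrix


def _cm(data, groups=None):
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    return CountMatrix(counts=df, groups=groups or {c: "A" for c in df.columns})


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_identical_samples_symmetric():
    cm = _cm({"s1": [10, 20, 30], "s2": [10, 20, 30]})
    expr = normalize(cm)
    assert expr.size_factors["s1"] == pytest.approx(expr.size_factors["s2"])
    assert np.allclose(expr.values["s1"], expr.values["s2"])


def test_normalize_scaled_sample_recovers_same_column():
    cm = _cm({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    expr = normalize(cm)
    assert expr.size_factors["s2"] / expr.size_factors["s1"] == pytest.approx(2.0)
    assert np.allclose(expr.values["s1"], expr.values["s2"], atol=1e-12)


def test_normalize_matches_hand_median_of_ratios():
    """Three-gene worked example against an explicit hand computation."""
    counts = {"s1": [100, 40, 10], "s2": [200, 90, 15]}
    cm = _cm(counts)
    expr = normalize(cm)
    # hand computation: geometric-mean reference, per-sample median ratio
    ref = [math.sqrt(a * b) for a, b in zip(counts["s1"], counts["s2"])]
    for s in ("s1", "s2"):
        ratios = sorted(c / r for c, r in zip(counts[s], ref))
        hand_sf = ratios[1]  # median of 3
        assert expr.size_factors[s] == pytest.approx(hand_sf, rel=1e-12)
        hand_col = [math.log2(c / hand_sf + 1.0) for c in counts[s]]
        assert np.allclose(expr.values[s], hand_col)


def test_normalize_scale_invariance_up_to_global_factor():
    """Rescaling one sample's library changes normalized values only by a
    single global factor c**(1/n) shared by every column (the overall scale
    of median-of-ratios size factors is arbitrary)."""
    rng = np.random.default_rng(0)
    base = rng.integers(10, 1000, size=(30, 4))
    c = 2.0
    groups = {s: "A" for s in "abcd"}
    e1 = normalize(CountMatrix(counts=pd.DataFrame(base, columns=list("abcd")),
                               groups=groups))
    scaled = base.copy()
    scaled[:, 2] *= int(c)
    e2 = normalize(CountMatrix(counts=pd.DataFrame(scaled, columns=list("abcd")),
                               groups=groups))
    # undo the pseudocount, compare on the count scale
    lin1 = 2.0 ** e1.values.to_numpy() - 1.0
    lin2 = 2.0 ** e2.values.to_numpy() - 1.0
    assert np.allclose(lin2, lin1 * c ** 0.25, rtol=1e-9)
    # and size factors: the scaled sample's factor grows by c^{(n-1)/n}
    assert e2.size_factors["c"] / e1.size_factors["c"] == pytest.approx(c ** 0.75)


def test_normalize_rejects_all_zero_sample():
    with pytest.raises(ValueError, match="all-zero"):
        normalize(_cm({"s1": [1, 2], "s2": [0, 0]}))


# ---------------------------------------------------------------------------
# z-scores and DEG filter
# ---------------------------------------------------------------------------


def _expr_two_groups(vals_a, vals_b):
    n_a, n_b = len(vals_a[0]), len(vals_b[0])
    cols = {f"a{i}": [v[i] for v in vals_a] for i in range(n_a)}
    cols |= {f"b{i}": [v[i] for v in vals_b] for i in range(n_b)}
    counts = pd.DataFrame({c: [100] * len(vals_a) for c in cols})
    counts.index = [f"g{i}" for i in range(len(vals_a))]
    groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
    cm = CountMatrix(counts=counts, groups=groups)
    expr = normalize(cm)
    expr.values = pd.DataFrame(cols, index=counts.index).astype(float)
    return expr


def test_gene_zscores_null_case_zero():
    expr = _expr_two_groups([[1.0, 2.0]], [[1.0, 2.0]])
    res = gene_zscores(expr, ("A", "B"))
    assert res["z"].iloc[0] == pytest.approx(0.0)


def test_gene_zscores_antisymmetric():
    expr = _expr_two_groups([[1.0, 2.0, 1.5]], [[3.0, 4.0, 2.5]])
    z_ab = gene_zscores(expr, ("A", "B"))["z"]
    z_ba = gene_zscores(expr, ("B", "A"))["z"]
    assert np.allclose(z_ab, -z_ba)


def test_gene_zscores_hand_pooled_variance():
    """{1,2} vs {3,4}: z = (1.5-3.5)/sqrt(0.5*(1/2+1/2)) = -2.8284."""
    expr = _expr_two_groups([[1.0, 2.0]], [[3.0, 4.0]])
    z = gene_zscores(expr, ("A", "B"))["z"].iloc[0]
    pooled_var = (0.5 + 0.5) / 2
    hand = (1.5 - 3.5) / math.sqrt(pooled_var * (0.5 + 0.5))
    assert z == pytest.approx(hand)


def test_gene_zscores_zero_variance_flagged():
    expr = _expr_two_groups([[1.0, 1.0]], [[1.0, 1.0]])
    expr.values.iloc[0] = [2.0, 2.0, 2.0, 2.0][: len(expr.values.columns)]
    res = gene_zscores(expr, ("A", "B"))
    assert bool(res["zero_variance"].iloc[0]) and res["z"].iloc[0] == 0.0


def test_gene_zscores_unknown_group():
    expr = _expr_two_groups([[1.0, 2.0]], [[3.0, 4.0]])
    with pytest.raises(ValueError):
        gene_zscores(expr, ("A", "C"))


def test_select_degs_boundary_rules():
    table = pd.DataFrame(
        {"log2fc": [2.0, 1.99, -2.5, 3.0, 0.1], "pvalue": [0.049, 0.001, 0.01, 0.05, 0.2]},
        index=[f"g{i}" for i in range(5)],
    )
    got = select_degs(table)
    # brute-force filter over the 5 rows
    expected = {
        g for g, lfc, p in zip(table.index, table["log2fc"], table["pvalue"])
        if abs(lfc) >= 2.0 and p < 0.05
    }
    assert got == expected
    assert "g0" in got       # lfc == 2.0 inclusive, p < 0.05 strict
    assert "g1" not in got   # below fold-change cutoff
    assert "g3" not in got   # p == 0.05 not selected


def test_de_table_contrast(toy_counts):
    from fluxaging.expression import normalize as _norm

    expr = _norm(toy_counts)
    t = de_table(expr, ("KO_old", "WT_old"))
    assert set(t.columns) == {"log2fc", "pvalue"}
    assert ((t["pvalue"] >= 0) & (t["pvalue"] <= 1)).all()
    # suppressed uptake gene of pathway 1 shows ~ -2 log2FC
    assert t.loc["g01_u_0", "log2fc"] == pytest.approx(-2.0, abs=0.8)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def _ranking_10():
    genes = [f"g{i}" for i in range(1, 11)]
    return dict(zip(genes, [float(s) for s in range(10, 0, -1)]))


def test_gsea_es_matches_bruteforce_running_sum():
    ranking = _ranking_10()
    sets = GeneSetCollection({"top2": ["g1", "g2"], "mid": ["g4", "g7"]})
    res = preranked_gsea(ranking, sets, weight=1.0, n_perm=50, min_size=2, seed=0)
    genes = sorted(ranking, key=lambda g: (-ranking[g], g))
    scores = [ranking[g] for g in genes]
    for name, members in sets.items():
        expected = es_bruteforce(genes, scores, set(members))
        assert res.loc[name, "es"] == pytest.approx(expected, abs=1e-12)
    # the top-2 prefix set attains the maximal ES of 1 by construction
    assert res.loc["top2", "es"] == pytest.approx(1.0)


def test_gsea_balanced_set_scores_below_concentrated_set():
    genes = [f"g{i}" for i in range(20)]
    ranking = dict(zip(genes, [1.0] * 20))  # flat |score|
    sets = GeneSetCollection(
        {"spread": genes[::5], "top": genes[:4]}  # uniform spacing vs prefix
    )
    res = preranked_gsea(ranking, sets, n_perm=50, min_size=3, seed=0)
    assert abs(res.loc["spread", "es"]) < res.loc["top", "es"]


def test_gsea_sign_recovery_planted_sets():
    genes = [f"g{i}" for i in range(40)]
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.standard_normal(40))[::-1]
        ranking = dict(zip(genes, scores))
        sets = GeneSetCollection({"top": genes[:5], "bottom": genes[-5:]})
        res = preranked_gsea(ranking, sets, n_perm=200, min_size=3, seed=seed)
        ok += (res.loc["top", "nes"] > 0) and (res.loc["bottom", "nes"] < 0)
    assert ok >= 19


def test_gsea_min_size_exclusion_reported():
    ranking = _ranking_10()
    sets = GeneSetCollection({"tiny": ["g1", "g2"], "ok": ["g1", "g2", "g3"]})
    res = preranked_gsea(ranking, sets, min_size=3, n_perm=50, seed=0)
    assert bool(res.loc["tiny", "excluded"]) and math.isnan(res.loc["tiny", "es"])
    assert not res.loc["ok", "excluded"]


def test_gsea_all_sets_too_small_warns():
    ranking = _ranking_10()
    sets = GeneSetCollection({"tiny": ["g1", "g2"]})
    with pytest.warns(UserWarning, match="min_size"):
        res = preranked_gsea(ranking, sets, min_size=5, n_perm=10, seed=0)
    assert res["excluded"].all()


def test_gsea_deterministic_given_seed():
    ranking = _ranking_10()
    sets = GeneSetCollection({"s": ["g2", "g5", "g9"]})
    a = preranked_gsea(ranking, sets, n_perm=100, seed=3)
    b = preranked_gsea(ranking, sets, n_perm=100, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_gsea_rejects_duplicate_genes():
    ranking = pd.Series([1.0, 2.0], index=["g1", "g1"])
    with pytest.raises(ValueError, match="duplicate"):
        preranked_gsea(ranking, GeneSetCollection({"s": ["g1"]}), min_size=1)
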