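import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import min_penalty_support_oracle
from fluxaging.context_model import (
    DEFAULT_FORCED_PATHWAYS,
    extract_context_model,
    score_reactions,
)
from fluxaging.expression import normalize
from fluxaging.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr
from fluxaging.synthetic_data import SyntheticDesign, make_toy_model, simulate_counts


def _flat_model(n, subsystem="S"):
    """n disconnected exchange reactions, one gene each (scoring testbed)."""
    mets = [Metabolite(f"m{i}") for i in range(n)]
    rxns = [
        Reaction(f"r{i}", subsystem=subsystem, upper_bound=10,
                 gpr=parse_gpr(f"gene{i}"), metabolites={f"m{i}": 1})
        for i in range(n)
    ]
    # add sinks so the model is usable, without GPRs
    return MetabolicModel(reactions=rxns, metabolites=mets)


def test_percentile_partition_100_distinct():
    """100 distinct evidence values split exactly 35 / 55 / 10."""
    m = _flat_model(100)
    expr = {f"gene{i}": float(i + 1) for i in range(100)}
    conf = score_reactions(m, expr)
    counts = conf.counts()
    assert counts == {3: 35, 2: 55, 1: 10}


def test_forced_subsystem_all_score3():
    m = _flat_model(10)
    expr = {f"gene{i}": float(i) for i in range(10)}
    conf = score_reactions(m, expr, forced_pathways=["S"])
    assert (conf.table["score"] == 3).all()
    assert conf.table["forced"].all()


def test_unknown_forced_pathway_lists_valid_labels():
    m = _flat_model(5)
    expr = {f"gene{i}": float(i) for i in range(5)}
    with pytest.raises(ValueError, match="valid labels"):
        score_reactions(m, expr, forced_pathways=["Nope"])


def test_score_partition_sums_to_total():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        m = _flat_model(n)
        # heavy ties on purpose
        expr = {f"gene{i}": float(rng.integers(0, 5)) for i in range(n)}
        conf = score_reactions(m, expr)
        assert int(conf.table["score"].isin([1, 2, 3]).sum()) == n


def test_tie_group_follows_average_rank_oracle():
    """Ties spanning the 35% boundary resolved by average ranks."""
    rng = np.random.default_rng(1)
    for _ in range(10):
        n = 10
        m = _flat_model(n)
        vals = rng.integers(0, 4, size=n).astype(float)
        expr = {f"gene{i}": vals[i] for i in range(n)}
        conf = score_reactions(m, expr)
        # independent oracle: sort-based average ranks from the top
        order = sorted(range(n), key=lambda i: -vals[i])
        avg_rank = {}
        i = 0
        while i < n:
            j = i
            while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            for k in range(i, j + 1):
                avg_rank[order[k]] = (i + j) / 2 + 1
            i = j + 1
        for i in range(n):
            pct = 100.0 * avg_rank[i] / n
            want = 3 if pct <= 35 + 1e-9 else (2 if pct <= 90 + 1e-9 else 1)
            assert conf.table["score"].iloc[i] == want


def test_missing_genes_imputed_with_minimum_and_reported():
    m = _flat_model(4)
    expr = {f"gene{i}": float(i + 1) for i in range(3)}  # gene3 missing
    conf = score_reactions(m, expr)
    assert conf.imputed_genes == ["gene3"]
    # imputed at the matrix minimum: cannot outrank any present gene
    assert conf.table["evidence"].iloc[3] == 1.0


def test_no_gpr_policy_median_vs_score2():
    mets = [Metabolite(f"m{i}") for i in range(4)]
    rxns = [
        Reaction("lo", upper_bound=10, gpr=parse_gpr("g1"), metabolites={"m0": 1}),
        Reaction("hi", upper_bound=10, gpr=parse_gpr("g2"), metabolites={"m1": 1}),
        Reaction("nogpr1", upper_bound=10, metabolites={"m2": 1}),
        Reaction("nogpr2", upper_bound=10, metabolites={"m3": 1}),
    ]
    m = MetabolicModel(reactions=rxns, metabolites=mets)
    conf_med = score_reactions(m, {"g1": 0.0, "g2": 10.0})
    assert conf_med.table.loc["nogpr1", "evidence"] == pytest.approx(5.0)  # median
    conf_s2 = score_reactions(m, {"g1": 0.0, "g2": 10.0}, no_gpr_policy="score2")
    assert conf_s2.table.loc["nogpr1", "score"] == 2
    assert conf_s2.table.loc["nogpr2", "score"] == 2


def test_invalid_percentile_cuts():
    m = _flat_model(3)
    expr = {f"gene{i}": float(i) for i in range(3)}
    with pytest.raises(ValueError):
        score_reactions(m, expr, percentile_cuts=(90, 35))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _support_testbed():
    """score-3 sink needs one upstream; two parallel candidates exist."""
    mets = [Metabolite("A")]
    rxns = [
        Reaction("up_used", upper_bound=10, metabolites={"A": 1}),
        Reaction("up_parallel", upper_bound=10, metabolites={"A": 1}),
        Reaction("sink", upper_bound=1000, metabolites={"A": -1}),
    ]
    return MetabolicModel(reactions=rxns, metabolites=mets)


def _manual_conf(model, scores, forced=frozenset()):
    from fluxaging.context_model import ReactionConfidence

    table = pd.DataFrame(
        {
            "evidence": [float(scores[r.id]) for r in model.reactions],
            "percentile": [50.0] * len(model.reactions),
            "score": [scores[r.id] for r in model.reactions],
            "forced": [r.id in forced for r in model.reactions],
            "has_gpr": [not r.gpr.is_empty for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
        },
        index=pd.Index(model.reaction_ids, name="reaction"),
    )
    return ReactionConfidence(table=table)


def test_extraction_includes_needed_support_excludes_parallel():
    m = _support_testbed()
    conf = _manual_conf(m, {"up_used": 1, "up_parallel": 1, "sink": 3})
    ctx = extract_context_model(m, conf)
    kept = set(ctx.reaction_ids)
    assert "sink" in kept
    assert len(kept & {"up_used", "up_parallel"}) == 1  # exactly one support
    assert not ctx.blocked


def test_extraction_prefers_cheaper_support():
    m = _support_testbed()
    conf = _manual_conf(m, {"up_used": 2, "up_parallel": 1, "sink": 3})
    ctx = extract_context_model(m, conf)
    assert "up_used" in ctx.reaction_ids  # score-2 (penalty 1) beats score-1 (100)
    assert "up_parallel" not in ctx.reaction_ids


def test_extraction_all_score3_keeps_everything(toy_model):
    conf = _manual_conf(toy_model, {r.id: 3 for r in toy_model.reactions})
    ctx = extract_context_model(toy_model, conf)
    assert set(ctx.reaction_ids) == set(toy_model.reaction_ids)
    assert not ctx.blocked


def test_extraction_reports_blocked_score3():
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("up", upper_bound=10, metabolites={"A": 1}),
        Reaction("sink", upper_bound=1000, metabolites={"A": -1}),
        Reaction("orphan", upper_bound=1000, metabolites={"B": -1}),  # no producer
    ]
    m = MetabolicModel(reactions=rxns, metabolites=mets)
    conf = _manual_conf(m, {"up": 2, "sink": 3, "orphan": 3})
    ctx = extract_context_model(m, conf)
    assert ctx.blocked == ["orphan"]
    assert "orphan" not in ctx.reaction_ids


def test_extraction_requires_score3_anchor(toy_model):
    conf = _manual_conf(toy_model, {r.id: 2 for r in toy_model.reactions})
    with pytest.raises(ValueError, match="score-3"):
        extract_context_model(toy_model, conf)


def test_retained_score3_re_verified_functional(toy_model, toy_counts):
    expr = normalize(toy_counts)
    for sample in ("WT_young_1", "KO_old_1"):
        conf = score_reactions(toy_model, expr.values[sample])
        ctx = extract_context_model(toy_model, conf)
        from fluxaging.flux_sim import fba_model

        for rid in ctx.reaction_ids:
            if conf.score(rid) == 3 and rid not in ctx.blocked:
                res = fba_model(ctx.model, rid, "max")
                assert res.ok and res.objective_value >= 1e-6


def test_forcing_monotonicity(toy_model, toy_counts):
    """Adding a forced subsystem never removes reactions from the context."""
    expr = normalize(toy_counts)
    col = expr.values["KO_old_1"]
    base_kept = set(
        extract_context_model(toy_model, score_reactions(toy_model, col)).reaction_ids
    )
    for sub in ("Fatty acid oxidation", "Citric Acid Cycle"):
        forced_kept = set(
            extract_context_model(
                toy_model, score_reactions(toy_model, col, forced_pathways=[sub])
            ).reaction_ids
        )
        assert base_kept <= forced_kept


def test_support_matches_exhaustive_minimum_penalty_oracle():
    """Layered random networks: LP support penalty equals subset-enumeration optimum."""
    rng = np.random.default_rng(42)
    n_checked = 0
    for inst in range(10):
        # layered network: m0 -> m1 -> m2, parallel unit reactions per layer
        n_layers = 2
        per_layer = int(rng.integers(2, 4))
        mets = [Metabolite(f"m{i}") for i in range(n_layers + 1)]
        rxns = [Reaction("src", upper_bound=10.0, metabolites={"m0": 1})]
        scores = {"src": 3}
        for layer in range(n_layers):
            for j in range(per_layer):
                rid = f"L{layer}_{j}"
                rxns.append(
                    Reaction(rid, upper_bound=10.0,
                             metabolites={f"m{layer}": -1, f"m{layer + 1}": 1})
                )
                scores[rid] = int(rng.choice([1, 2, 2]))
        rxns.append(Reaction("target", upper_bound=1000.0,
                             metabolites={f"m{n_layers}": -1}))
        scores["target"] = 3
        m = MetabolicModel(reactions=rxns, metabolites=mets)
        assert len(m.reactions) <= 12
        conf = _manual_conf(m, scores)
        ctx = extract_context_model(m, conf)
        support = ctx.per_target_support["target"]
        oracle = min_penalty_support_oracle(m, conf, "target", demand=1.0)
        assert oracle is not None
        pen = {1: 100.0, 2: 1.0}
        impl_penalty = sum(pen[scores[r]] for r in support)
        assert impl_penalty == pytest.approx(oracle[0])
        n_checked += 1
    assert n_checked == 10
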