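"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: ranks are computed
by explicit sorting, the enrichment running sum by a literal loop, and the
minimum-penalty support by exhaustive subset enumeration, so agreement
with the implementation is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def vdw_independent(groups):
    """Loop-based Van der Waerden statistic and chi-square p-value."""
    pooled = [float(x) for g in groups for x in g]
    n = len(pooled)
    # average ranks by explicit sorting
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    scores = [stats.norm.ppf(r / (n + 1.0)) for r in ranks]
    s2 = sum(a * a for a in scores) / (n - 1)
    t = 0.0
    pos = 0
    for g in groups:
        m = len(g)
        mean_j = sum(scores[pos : pos + m]) / m
        t += m * mean_j * mean_j
        pos += m
    t /= s2
    k = len(groups)
    return t, float(stats.chi2.sf(t, k - 1))


def es_bruteforce(ranked_genes, ranked_scores, member_set, weight=1.0):
    """Literal running-sum enrichment score over every list position."""
    n = len(ranked_genes)
    hits = [g in member_set for g in ranked_genes]
    n_hit = sum(hits)
    denom = sum(abs(s) ** weight for g, s in zip(ranked_genes, ranked_scores) if g in member_set)
    running = 0.0
    best = 0.0
    for g, s, h in zip(ranked_genes, ranked_scores, hits):
        if h:
            running += (abs(s) ** weight) / denom if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def min_penalty_support_oracle(model, conf, target, demand, penalty_low=100.0, penalty_mid=1.0):
    """Exhaustively find the minimum total penalty over support subsets.

    A subset S of score-1/2 reactions is feasible when the target can carry
    ``demand`` flux using only score-3 reactions plus S (all other
    reactions clamped to zero). Returns (min_penalty, subset) or None when
    no subset is feasible. Enumerated in increasing-penalty order.
    """
    from fluxaging.flux_sim import fba_model
    from fluxaging.model_io import MetabolicModel, Metabolite, Reaction

    scores = conf.table["score"]
    penalized = [r.id for r in model.reactions if scores[r.id] < 3]
    pen = {rid: penalty_low if scores[rid] == 1 else penalty_mid for rid in penalized}
    base = {r.id for r in model.reactions if scores[r.id] == 3}

    def feasible(subset):
        allowed = base | set(subset)
        rxns = []
        for r in model.reactions:
            lb, ub = (r.lower_bound, r.upper_bound) if r.id in allowed else (0.0, 0.0)
            rxns.append(Reaction(r.id, r.name, r.subsystem, lb, ub, r.gpr, dict(r.metabolites)))
        clamped = MetabolicModel(
            reactions=rxns,
            metabolites=[Metabolite(m.id, m.name, m.compartment) for m in model.metabolites],
        )
        res = fba_model(clamped, target, "max")
        return res.ok and res.objective_value >= demand - 1e-9

    subsets = []
    for k in range(len(penalized) + 1):
        for combo in itertools.combinations(penalized, k):
            subsets.append((sum(pen[r] for r in combo), combo))
    subsets.sort(key=lambda x: (x[0], x[1]))
    for total, combo in subsets:
        if feasible(combo):
            return total, set(combo)
    return None
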