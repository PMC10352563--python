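"""Expression-percentile confidence scoring and context-model extraction.

Reactions receive a confidence score in {3, 2, 1} from the percentile rank
of their GPR-evaluated expression evidence: top 35% of reactions score 3
(high), 35-90% score 2 (medium), 90-100% score 1 (low). A configurable
list of "vital" subsystems can be forced to score 3 regardless of evidence
(defaults to the twelve pathways required for simulation stability on
genome-scale models).

Context extraction is a deterministic cost-optimization reaction dependency
assessment (CORDA-style): each high-confidence reaction is kept functional
at minimal penalized usage of medium- (penalty 1) and low-confidence
(penalty 100) reactions, solved as a two-stage LP per target rather than
by stochastic iterative inclusion. High-confidence reactions that cannot
carry flux in the base model are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .flux_sim import fba_model
from .model_io import MetabolicModel

__all__ = [
    "DEFAULT_FORCED_PATHWAYS",
    "DEFAULT_PERCENTILE_CUTS",
    "ReactionConfidence",
    "ContextModel",
    "score_reactions",
    "extract_context_model",
]

#: Vital pathways granted full activation for simulation stability.
DEFAULT_FORCED_PATHWAYS = (
    "Oxidative Phosphorylation",
    "Citric Acid Cycle",
    "Glycolysis/Gluconeogenesis",
    "CoA Biosynthesis",
    "CoA Catabolism",
    "NAD Metabolism",
    "Fatty Acid Metabolism",
    "Fatty acid activation",
    "Fatty acid elongation",
    "Fatty acid oxidation",
    "ROS Detoxification",
    "Biomass and maintenance functions",
)

#: Percentile boundaries of the three confidence tiers (top 35%, 35-90%).
DEFAULT_PERCENTILE_CUTS = (35.0, 90.0)

_PCT_TOL = 1e-9  # a reaction exactly at a cut falls in the higher tier


@dataclass
class ReactionConfidence:
    """Per-reaction evidence, percentile rank, score in {3,2,1}, forced flag."""

    table: pd.DataFrame  # index: reaction id; columns: evidence, percentile, score, forced
    imputed_genes: list = field(default_factory=list)

    def __post_init__(self):
        scores = self.table["score"]
        if not scores.isin([1, 2, 3]).all():
            raise ValueError("confidence scores must be in {1, 2, 3}")
        if (self.table.loc[self.table["forced"], "score"] != 3).any():
            raise ValueError("forced reactions must score 3")

    def score(self, rid: str) -> int:
        return int(self.table.at[rid, "score"])

    def reactions_with_score(self, score: int) -> list:
        return list(self.table.index[self.table["score"] == score])

    def counts(self) -> dict:
        return self.table["score"].value_counts().to_dict()


def score_reactions(
    model: MetabolicModel,
    expression: Mapping[str, float] | pd.Series,
    forced_pathways: Sequence[str] = (),
    percentile_cuts: tuple = DEFAULT_PERCENTILE_CUTS,
    no_gpr_policy: str = "median",
    missing_value: float | None = None,
) -> ReactionConfidence:
    """Score every reaction from expression evidence plus forcing.

    ``expression`` maps gene id -> normalized value (one sample's column or
    a group mean). Genes referenced by GPR rules but absent from the map
    are imputed with ``missing_value`` (default: the map-wide minimum, so
    absent evidence never promotes a reaction) and reported. Reactions
    without a GPR get the median evidence of GPR-backed reactions
    (``no_gpr_policy="median"``) or a fixed score of 2 (``"score2"``).
    Percentile ranks use average ranks for ties over all reactions; a
    reaction exactly at the 35% boundary scores 3.
    """
    lo_cut, hi_cut = percentile_cuts
    if not (0 < lo_cut < hi_cut < 100):
        raise ValueError("percentile cuts must satisfy 0 < low < high < 100")
    if no_gpr_policy not in ("median", "score2"):
        raise ValueError("no_gpr_policy must be 'median' or 'score2'")
    valid_subsystems = set(model.subsystems)
    unknown = [s for s in forced_pathways if s not in valid_subsystems]
    if unknown:
        raise ValueError(
            f"forced pathway(s) {unknown} not in model; valid labels: "
            f"{sorted(valid_subsystems)}"
        )

    expr = dict(pd.Series(expression, dtype=float).items())
    if not expr:
        raise ValueError("empty expression map")
    impute = min(expr.values()) if missing_value is None else missing_value

    imputed: set = set()
    evidence = np.full(len(model.reactions), np.nan)
    has_gpr = np.zeros(len(model.reactions), dtype=bool)
    for i, r in enumerate(model.reactions):
        if r.gpr.is_empty:
            continue
        has_gpr[i] = True
        imputed |= r.gpr.genes - expr.keys()
        evidence[i] = r.gpr.evaluate(expr, missing=impute)

    if has_gpr.any():
        median_ev = float(np.median(evidence[has_gpr]))
    else:
        median_ev = 0.0
    evidence[~has_gpr] = median_ev

    # percentile rank from the top: highest evidence -> smallest percentile
    ranks = stats.rankdata(-evidence, method="average")
    pct = 100.0 * ranks / len(evidence)
    score = np.where(pct <= lo_cut + _PCT_TOL, 3, np.where(pct <= hi_cut + _PCT_TOL, 2, 1))
    if no_gpr_policy == "score2":
        score[~has_gpr] = 2

    forced_set = set(forced_pathways)
    forced = np.array([r.subsystem in forced_set for r in model.reactions])
    score[forced] = 3

    table = pd.DataFrame(
        {
            "evidence": evidence,
            "percentile": pct,
            "score": score.astype(int),
            "forced": forced,
            "has_gpr": has_gpr,
            "subsystem": [r.subsystem for r in model.reactions],
        },
        index=pd.Index(model.reaction_ids, name="reaction"),
    )
    return ReactionConfidence(table=table, imputed_genes=sorted(imputed))


# ---------------------------------------------------------------------------
# Context extraction
# ---------------------------------------------------------------------------


@dataclass
class ContextModel:
    """Extracted submodel plus retention provenance and blocked reactions."""

    model: MetabolicModel
    provenance: pd.DataFrame  # index rid; columns score, forced, as_support
    blocked: list  # score-3 reactions that cannot carry flux
    per_target_support: dict  # score-3 rid -> frozenset of support rids

    @property
    def reaction_ids(self) -> list:
        return self.model.reaction_ids


def _min_penalty_support(
    model: MetabolicModel,
    penalties: np.ndarray,
    target_index: int,
    demand: float,
    direction: int,
) -> np.ndarray | None:
    """Minimize sum(penalty * |v|) s.t. Sv=0, bounds, direction*v_target >= demand.

    Returns the flux vector at the optimum, or None if infeasible. Flux
    magnitudes enter via the standard split t >= v, t >= -v on penalized
    reactions only.
    """
    S = model.S
    n = S.shape[1]
    pen_idx = np.flatnonzero(penalties > 0)
    m = len(pen_idx)
    c = np.concatenate([np.zeros(n), penalties[pen_idx]])
    A_eq = np.hstack([S, np.zeros((S.shape[0], m))])
    A_ub = np.zeros((2 * m, n + m))
    for k, j in enumerate(pen_idx):
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + k] = -1.0
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + k] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    lbt, ubt = bounds[target_index]
    if direction > 0:
        bounds[target_index] = (max(lbt, demand), ubt)
    else:
        bounds[target_index] = (lbt, min(ubt, -demand))
    bounds += [(0.0, None)] * m
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub if m else None,
        b_ub=np.zeros(2 * m) if m else None,
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return np.asarray(res.x[:n])


def extract_context_model(
    model: MetabolicModel,
    conf: ReactionConfidence,
    penalty_low: float = 100.0,
    penalty_mid: float = 1.0,
    flux_threshold: float = 1e-6,
    support_flux: float = 1.0,
) -> ContextModel:
    """Extract the context-specific submodel anchored on score-3 reactions.

    For each score-3 reaction (both directions for reversible ones): find
    its flux capacity; if >= ``flux_threshold``, re-solve at demand
    ``min(capacity, support_flux)`` minimizing penalty-weighted absolute
    flux on score-1/2 reactions, and accumulate every score-1/2 reaction
    carrying >= ``flux_threshold`` flux as support. Score-2 reactions not
    used as support are retained if they can independently carry flux when
    added to the candidate submodel. Score-1 reactions never used as
    support are excluded. Score-3 reactions with no feasible flux are
    returned in ``blocked``.
    """
    missing = set(model.reaction_ids) - set(conf.table.index)
    if missing:
        raise ValueError(f"confidence table does not cover reaction(s) {sorted(missing)}")
    base = fba_model(model, {r.id: 0.0 for r in model.reactions[:1]}, "max")
    if not base.ok:
        raise ValueError("base model is infeasible")
    score3 = [r.id for r in model.reactions if conf.score(r.id) == 3]
    if not score3:
        raise ValueError("no score-3 reactions: nothing to anchor the context model")

    scores = conf.table["score"]
    penalties = np.array(
        [
            penalty_low if scores[rid] == 1 else (penalty_mid if scores[rid] == 2 else 0.0)
            for rid in model.reaction_ids
        ]
    )

    support: set = set()
    blocked: list = []
    per_target: dict = {}
    for rid in score3:
        j = model.reaction_index(rid)
        r = model.reactions[j]
        this_support: set = set()
        achieved = False
        directions = [1] + ([-1] if r.reversible else [])
        for direction in directions:
            cap = fba_model(model, rid, "max" if direction > 0 else "min")
            if not cap.ok:
                continue
            capacity = direction * cap.objective_value
            if capacity < flux_threshold:
                continue
            achieved = True
            demand = min(capacity, support_flux)
            v = _min_penalty_support(model, penalties, j, demand, direction)
            if v is None:  # numerically infeasible at demand; retry at threshold
                v = _min_penalty_support(model, penalties, j, flux_threshold, direction)
            if v is not None:
                used = {
                    model.reaction_ids[i]
                    for i in np.flatnonzero(np.abs(v) >= flux_threshold)
                    if scores[model.reaction_ids[i]] < 3
                }
                this_support |= used
        if achieved:
            support |= this_support
            per_target[rid] = frozenset(this_support)
        else:
            blocked.append(rid)

    retained = (set(score3) - set(blocked)) | support

    # score-2 reactions kept if independently functional in the candidate model
    candidates = [
        r.id for r in model.reactions if scores[r.id] == 2 and r.id not in retained
    ]
    independent: set = set()
    for rid in candidates:
        sub = model.submodel(retained | {rid}, id_suffix="probe")
        res = fba_model(sub, rid, "max")
        best = res.objective_value if res.ok else 0.0
        if sub.reaction(rid).reversible:
            res_min = fba_model(sub, rid, "min")
            if res_min.ok:
                best = max(best, -res_min.objective_value)
        if best >= flux_threshold:
            independent.add(rid)
    retained |= independent

    submodel = model.submodel(retained, id_suffix="context")

    # re-verify the contract: every retained score-3 reaction is functional
    for rid in set(score3) - set(blocked):
        res = fba_model(submodel, rid, "max")
        best = res.objective_value if res.ok else 0.0
        if submodel.reaction(rid).reversible:
            res_min = fba_model(submodel, rid, "min")
            if res_min.ok:
                best = max(best, -res_min.objective_value)
        if best < flux_threshold:
            raise RuntimeError(
                f"extraction invariant violated: score-3 reaction {rid} cannot "
                "carry flux in the extracted submodel"
            )

    prov = pd.DataFrame(
        {
            "score": [int(scores[rid]) for rid in submodel.reaction_ids],
            "forced": [bool(conf.table.at[rid, "forced"]) for rid in submodel.reaction_ids],
            "as_support": [rid in support for rid in submodel.reaction_ids],
        },
        index=pd.Index(submodel.reaction_ids, name="reaction"),
    )
    return ContextModel(
        model=submodel, provenance=prov, blocked=blocked, per_target_support=per_target
    )
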