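"""Flux balance analysis and per-reaction flux profiling.

FBA solves ``max/min c'v  s.t.  S v = 0, lb <= v <= ub`` with scipy's HiGHS
backend (deterministic for fixed inputs). Flux profiling optimizes every
reaction of a context model in turn and records its optimal ("capacity")
flux; only objective values are contract-guaranteed, since non-objective
components of an optimal basis are not unique under alternate optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = ["FbaProblem", "FbaResult", "fba", "fba_model", "profile_fluxes", "atp_capacity"]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FbaProblem:
    """Bare LP form of an FBA instance."""

    S: np.ndarray  # metabolites x reactions
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    sense: str = "max"  # or "min"

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        n = self.S.shape[1]
        if not (len(self.lower) == len(self.upper) == len(self.objective) == n):
            raise ValueError("bounds/objective length must match number of reactions")
        if self.sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")


@dataclass
class FbaResult:
    objective_value: float
    fluxes: np.ndarray | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def fba(problem: FbaProblem) -> FbaResult:
    """Solve one FBA LP; returns objective value, flux vector and status."""
    sign = -1.0 if problem.sense == "max" else 1.0
    res = linprog(
        sign * problem.objective,
        A_eq=problem.S,
        b_eq=np.zeros(problem.S.shape[0]),
        bounds=list(zip(problem.lower, problem.upper)),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FbaResult(np.nan, None, status)
    return FbaResult(float(sign * res.fun), np.asarray(res.x), "optimal")


def fba_model(
    model: MetabolicModel,
    objective: Mapping[str, float] | str,
    sense: str = "max",
) -> FbaResult:
    """FBA on a :class:`MetabolicModel`; objective by reaction id or id->coef map."""
    n = len(model.reactions)
    c = np.zeros(n)
    if isinstance(objective, str):
        c[model.reaction_index(objective)] = 1.0
    else:
        for rid, coef in objective.items():
            c[model.reaction_index(rid)] = coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return fba(FbaProblem(model.S, lb, ub, c, sense))


def profile_fluxes(
    model: MetabolicModel,
    flux_threshold: float = 1e-6,
    maximize_only: bool = False,
) -> tuple[dict, dict]:
    """Per-reaction flux profile of a (context) model.

    Each reaction is optimized as the objective. Irreversible reactions are
    maximized; for reversible ones both directions are solved and the signed
    optimum of larger magnitude is reported (ties favor the maximization),
    unless ``maximize_only`` is set. Returns ``(fluxes, status)`` dicts keyed
    by reaction id; blocked or failed reactions get flux 0.0 with a
    non-"optimal" status ("blocked" when the optimum is below threshold).
    """
    fluxes: dict = {}
    status: dict = {}
    for r in model.reactions:
        res_max = fba_model(model, r.id, "max")
        best = res_max.objective_value if res_max.ok else np.nan
        st = res_max.status
        if r.reversible and not maximize_only:
            res_min = fba_model(model, r.id, "min")
            if res_min.ok:
                vmin = res_min.objective_value
                if not res_max.ok or abs(vmin) > abs(best):
                    best, st = vmin, res_min.status
        if st != "optimal" or not np.isfinite(best):
            fluxes[r.id] = 0.0
            status[r.id] = st if st != "optimal" else "numerical"
        elif abs(best) < flux_threshold:
            fluxes[r.id] = 0.0
            status[r.id] = "blocked"
        else:
            fluxes[r.id] = float(best)
            status[r.id] = "optimal"
    return fluxes, status


def atp_capacity(model: MetabolicModel) -> float:
    """Maximal flux of the ATP-maintenance pseudoreaction (ATP synthesis capacity)."""
    if model.atpm_id is None:
        raise ValueError("model declares no atpm_id (ATP-maintenance pseudoreaction)")
    res = fba_model(model, model.atpm_id, "max")
    if not res.ok:
        return 0.0
    return res.objective_value
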