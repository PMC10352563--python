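"""Constraint-based model I/O, GPR rule parsing/evaluation, GMT gene sets.

A :class:`MetabolicModel` carries the stoichiometric matrix ``S``
(metabolites x reactions), per-reaction flux bounds in mmol/gDW/h,
gene-protein-reaction (GPR) boolean rules and pathway ("subsystem") labels.
Models are read from a documented JSON dialect (see ``docs/methods.md``) or
from SBML Level 3 with the fbc package; gene-set collections come from GMT
files. All readers transparently accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "GprRule",
    "GprParseError",
    "ModelValidationError",
    "GeneSetCollection",
    "parse_gpr",
    "eval_gpr",
    "read_model",
    "write_model",
    "read_gmt",
    "DEFAULT_UPPER",
]

#: COBRA-community sentinel for an effectively unbounded flux.
DEFAULT_UPPER = 1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, bad bounds...)."""


class GprParseError(ValueError):
    """A GPR rule string could not be parsed; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


@dataclass(frozen=True)
class GprRule:
    """Boolean gene association: leaves are gene ids, nodes are AND/OR.

    The tree is stored as nested tuples: a leaf is a gene id string, an
    internal node is ``("and", child, child, ...)`` or ``("or", ...)`` with
    at least two children. ``root is None`` encodes the empty rule (no gene
    evidence attached to the reaction).
    """

    root: object | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def genes(self) -> frozenset:
        out: set = set()

        def walk(node):
            if isinstance(node, str):
                out.add(node)
            elif node is not None:
                for child in node[1:]:
                    walk(child)

        walk(self.root)
        return frozenset(out)

    def to_string(self) -> str:
        def fmt(node, parent_op=None):
            if isinstance(node, str):
                return node
            op = node[0]
            inner = f" {op} ".join(fmt(c, op) for c in node[1:])
            # parenthesize OR under AND to preserve precedence on re-parse
            if parent_op == "and" and op == "or":
                return f"({inner})"
            return inner

        return "" if self.root is None else fmt(self.root)

    def evaluate(self, expr: Mapping[str, float], missing: float | None = None) -> float:
        """AND -> min of children, OR -> max; empty rule -> NaN sentinel."""
        if self.root is None:
            return math.nan

        def ev(node) -> float:
            if isinstance(node, str):
                if node in expr:
                    return float(expr[node])
                if missing is None:
                    raise KeyError(f"gene {node!r} absent from expression map")
                return float(missing)
            op = node[0]
            vals = [ev(c) for c in node[1:]]
            return min(vals) if op == "and" else max(vals)

        return ev(self.root)


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GprRule:
    """Parse a COBRA-convention GPR string into a :class:`GprRule`.

    Case-insensitive ``and``/``or`` with standard AND-over-OR precedence;
    an empty/whitespace string yields the empty rule.
    """
    if text is None or not text.strip():
        return GprRule(None)
    tokens = _tokenize(text)
    idx = 0

    def peek():
        return tokens[idx][0].lower() if idx < len(tokens) else None

    def expect_operand():
        nonlocal idx
        if idx >= len(tokens):
            raise GprParseError("unexpected end of rule", len(text))
        tok, pos = tokens[idx]
        low = tok.lower()
        if low == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GprParseError("unbalanced parentheses", pos)
            idx += 1
            return node
        if low in ("and", "or", ")"):
            raise GprParseError(f"dangling operator or misplaced {tok!r}", pos)
        idx += 1
        return tok

    def parse_and():
        nonlocal idx
        children = [expect_operand()]
        while peek() == "and":
            idx += 1
            children.append(expect_operand())
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:  # flatten nested same-op nodes
            if isinstance(c, tuple) and c[0] == "and":
                flat.extend(c[1:])
            else:
                flat.append(c)
        return ("and", *flat)

    def parse_or():
        nonlocal idx
        children = [parse_and()]
        while peek() == "or":
            idx += 1
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:
            if isinstance(c, tuple) and c[0] == "or":
                flat.extend(c[1:])
            else:
                flat.append(c)
        return ("or", *flat)

    root = parse_or()
    if idx != len(tokens):
        raise GprParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return GprRule(root)


def eval_gpr(rule: GprRule, expr: Mapping[str, float], missing: float | None = None) -> float:
    """Evaluate a rule on per-gene expression values (AND=min, OR=max)."""
    return rule.evaluate(expr, missing=missing)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    name: str = ""
    subsystem: str = "unassigned"
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gpr: GprRule = field(default_factory=GprRule)
    #: metabolite id -> stoichiometric coefficient (negative = consumed)
    metabolites: dict = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """In-memory constraint-based model (see module docstring)."""

    reactions: list
    metabolites: list
    atpm_id: str | None = None
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> frozenset:
        out: set = set()
        for r in self.reactions:
            out |= r.gpr.genes
        return frozenset(out)

    @property
    def subsystems(self) -> list:
        seen: dict = {}
        for r in self.reactions:
            seen.setdefault(r.subsystem, None)
        return list(seen)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index(rid)]

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model") from None

    @property
    def S(self) -> np.ndarray:
        """Dense stoichiometric matrix, metabolites x reactions."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.metabolites.items():
                S[met_index[mid], j] = coef
        return S

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise ModelValidationError(f"duplicate reaction id(s): {dup}")
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dup = sorted({x for x in mids if mids.count(x) > 1})
            raise ModelValidationError(f"duplicate metabolite id(s): {dup}")
        known = set(mids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower bound {r.lower_bound} > upper {r.upper_bound}"
                )
            if not r.subsystem:
                r.subsystem = "unassigned"
            unknown = set(r.metabolites) - known
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id} references unknown metabolite(s) {sorted(unknown)}"
                )
        if self.atpm_id is not None and self.atpm_id not in set(rids):
            raise ModelValidationError(f"atpm_id {self.atpm_id!r} not a reaction id")
        self._rxn_index = {rid: i for i, rid in enumerate(rids)}

    # -- derivation ------------------------------------------------------
    def submodel(self, reaction_ids: Iterable[str], id_suffix: str = "sub") -> "MetabolicModel":
        """Subset to the given reactions, dropping now-unused metabolites."""
        keep = set(reaction_ids)
        missing = keep - set(self.reaction_ids)
        if missing:
            raise KeyError(f"unknown reaction id(s) {sorted(missing)}")
        rxns = [r for r in self.reactions if r.id in keep]
        used = set()
        for r in rxns:
            used |= set(r.metabolites)
        mets = [m for m in self.metabolites if m.id in used]
        atpm = self.atpm_id if self.atpm_id in keep else None
        return MetabolicModel(
            reactions=[
                Reaction(r.id, r.name, r.subsystem, r.lower_bound, r.upper_bound,
                         r.gpr, dict(r.metabolites))
                for r in rxns
            ],
            metabolites=[Metabolite(m.id, m.name, m.compartment) for m in mets],
            atpm_id=atpm,
            id=f"{self.id}_{id_suffix}",
        )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        raw_mets = data["metabolites"]
        raw_rxns = data["reactions"]
    except KeyError as e:
        raise ModelValidationError(f"model JSON missing required key {e}") from None
    mets = [Metabolite(m["id"], m.get("name", ""), m.get("compartment", "")) for m in raw_mets]
    rxns = []
    for rec in raw_rxns:
        if "id" not in rec:
            raise ModelValidationError(f"reaction record without id: {rec}")
        reversible = bool(rec.get("reversible", rec.get("lower_bound", 0) < 0))
        lb = rec.get("lower_bound", -DEFAULT_UPPER if reversible else 0.0)
        ub = rec.get("upper_bound", DEFAULT_UPPER)
        rxns.append(
            Reaction(
                id=rec["id"],
                name=rec.get("name", ""),
                subsystem=rec.get("subsystem") or "unassigned",
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=parse_gpr(rec.get("gene_reaction_rule", "")),
                metabolites={k: float(v) for k, v in rec.get("metabolites", {}).items()},
            )
        )
    return MetabolicModel(
        reactions=rxns,
        metabolites=mets,
        atpm_id=data.get("atpm_id"),
        id=data.get("id", "model"),
    )


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "atpm_id": model.atpm_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "metabolites": r.metabolites,
            }
            for r in model.reactions
        ],
    }


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------


def _gpr_from_association(assoc) -> object | None:
    import libsbml

    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        return assoc.getGeneProduct()
    children = [
        _gpr_from_association(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    op = "and" if assoc.isFbcAnd() else "or"
    return (op, *children)


def _read_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(_open_text(path).read())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError("SBML file contains no model element")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    gene_labels = {}
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    # subsystems from the SBML groups package, when present
    subsystem_of: dict = {}
    gplug = sbml_model.getPlugin("groups")
    if gplug is not None:
        for i in range(gplug.getNumGroups()):
            grp = gplug.getGroup(i)
            label = grp.getName() or grp.getId()
            for j in range(grp.getNumMembers()):
                subsystem_of[grp.getMember(j).getIdRef()] = label

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mets.append(Metabolite(sp.getId(), sp.getName() or "", sp.getCompartment() or ""))
    met_ids = {m.id for m in mets}

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rplug = rx.getPlugin("fbc")
        lb = ub = None
        root = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                raw = _gpr_from_association(gpa.getAssociation())

                def relabel(node):
                    if isinstance(node, str):
                        return gene_labels.get(node, node)
                    return (node[0], *[relabel(c) for c in node[1:]])

                root = relabel(raw) if raw is not None else None
        reversible = rx.getReversible() if rx.isSetReversible() else True
        if lb is None:
            lb = -DEFAULT_UPPER if reversible else 0.0
        if ub is None:
            ub = DEFAULT_UPPER
        stoich: dict = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                subsystem=subsystem_of.get(rx.getId(), "unassigned"),
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=GprRule(root),
                metabolites=stoich,
            )
        )
    return MetabolicModel(reactions=rxns, metabolites=mets, id=sbml_model.getId() or "model")


# ---------------------------------------------------------------------------
# Public readers/writers
# ---------------------------------------------------------------------------


def read_model(path, dialect: str | None = None) -> MetabolicModel:
    """Read a model from JSON (repo dialect) or SBML L3+fbc.

    ``dialect`` is ``"json"`` or ``"sbml"``; if omitted it is inferred from
    the file extension (``.xml``/``.sbml`` -> SBML, otherwise JSON).
    """
    path = Path(path)
    if dialect is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        dialect = "sbml" if stem.endswith((".xml", ".sbml")) else "json"
    if dialect == "sbml":
        return _read_sbml(path)
    if dialect == "json":
        with _open_text(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as e:
                raise ModelValidationError(f"malformed model JSON: {e}") from None
        return _model_from_dict(data)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'json' or 'sbml')")


def write_model(model: MetabolicModel, path) -> None:
    """Write the model in the repo JSON dialect (gzip if path ends in .gz)."""
    with _open_text(path, "wt") as fh:
        json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway lists); insertion-ordered, unique names."""

    sets: dict

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ModelValidationError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def filtered(self, universe: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if len(inter) >= min_size:
                kept[name] = inter
        return GeneSetCollection(kept)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, tab-separated name, description, members."""
    sets: dict = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ModelValidationError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ModelValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise ModelValidationError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description, *members]) + "\n")
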