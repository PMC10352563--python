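"""Synthetic toy models and RNA-seq-like count matrices with planted signal.

The generator emulates the statistical design of the mouse study this
pipeline targets: four groups (wild-type and knockout, young and aged) with
a small number of replicate libraries each, negative-binomial counts, and a
planted log2-fold suppression of the genes of designated metabolic
subsystems in the aged-knockout group only.

Toy metabolic models are built as independent linear pathways with known
optimal fluxes (each pathway's maximal sink flux equals its uptake bound),
so flux-profiling results can be checked analytically. Every uptake, chain
and sink reaction carries a GPR over fresh genes whose baseline expression
follows a fixed log2 offset per chain role; this gives each pathway a
stable high-expression "anchor" reaction, standing in for the expressed
transcriptome background a genome-scale model would provide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, Metabolite, Reaction, parse_gpr

__all__ = [
    "GROUP_LABELS",
    "DEFAULT_SUPPRESSED",
    "DEFAULT_SUBSYSTEMS",
    "SyntheticDesign",
    "CountMatrix",
    "make_toy_model",
    "simulate_counts",
    "gene_log2_offset",
]

#: Group labels in fixed order: wild-type/knockout x young/aged.
GROUP_LABELS = ("WT_young", "KO_young", "WT_old", "KO_old")

#: Subsystems whose genes are suppressed in the aged-knockout group.
DEFAULT_SUPPRESSED = (
    "Fatty acid oxidation",
    "Citric Acid Cycle",
    "Carnitine shuttle",
    "NAD Metabolism",
)

#: Subsystem labels cycled over toy pathways (mitochondria-flavored first).
DEFAULT_SUBSYSTEMS = (
    "Fatty acid oxidation",
    "Citric Acid Cycle",
    "Carnitine shuttle",
    "NAD Metabolism",
    "Glycolysis/Gluconeogenesis",
    "Oxidative Phosphorylation",
    "Sphingolipid metabolism",
    "Fatty acid elongation",
    "ROS Detoxification",
    "Pyruvate Metabolism",
    "Purine Metabolism",
    "Cholesterol Metabolism",
)

#: Subsystem of the ATP-maintenance pseudoreaction.
ATPM_SUBSYSTEM = "Biomass and maintenance functions"

# log2 expression offsets by reaction role: the uptake gene is the pathway's
# high-expression anchor; chain genes ramp downward; the sink sits between.
_UPTAKE_OFFSET = 2.0
_SINK_OFFSET = 1.5
_CHAIN_SPAN = (1.0, -1.0)

_GENE_RE = re.compile(r"^g(\d+)_(u|s|c(\d+)of(\d+))_(\d+)$")


def gene_log2_offset(gene_id: str) -> float:
    """Baseline log2 expression offset encoded in a toy-model gene id."""
    m = _GENE_RE.match(gene_id)
    if m is None:
        raise ValueError(f"not a toy-model gene id: {gene_id!r}")
    role = m.group(2)
    if role == "u":
        return _UPTAKE_OFFSET
    if role == "s":
        return _SINK_OFFSET
    j, L = int(m.group(3)), int(m.group(4))
    if L == 1:
        return 0.0
    hi, lo = _CHAIN_SPAN
    return hi + (lo - hi) * (j - 1) / (L - 1)


@dataclass
class SyntheticDesign:
    """Study design of the synthetic count matrix.

    Defaults mirror the target study: four genotype/age groups with two
    replicate libraries each, NB dispersion 0.1, and a -2 log2-fold
    suppression of four mitochondria-associated subsystems in the aged
    knockout. The replicate count is a parameter because the study is
    ambiguous between its 2 libraries and 5 animals per condition; power
    analyses should use >=4 (see docs/methods.md).
    """

    replicates: int = 2
    group_labels: Sequence[str] = GROUP_LABELS
    suppressed_subsystems: Sequence[str] = DEFAULT_SUPPRESSED
    suppression_lfc: float = -2.0
    suppressed_group: str = "KO_old"
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.suppression_lfc > 0:
            raise ValueError("suppression_lfc must be <= 0")
        if self.suppressed_group not in self.group_labels:
            raise ValueError(
                f"suppressed_group {self.suppressed_group!r} not in group labels"
            )

    @property
    def samples(self) -> list:
        return [f"{g}_{i + 1}" for g in self.group_labels for i in range(self.replicates)]

    @property
    def groups(self) -> dict:
        return {f"{g}_{i + 1}": g for g in self.group_labels for i in range(self.replicates)}


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus a sample->group map."""

    counts: pd.DataFrame  # genes x samples, int
    groups: dict  # sample id -> group label

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    @property
    def genes(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def to_tsv(self, counts_path, groups_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        pd.Series(self.groups, name="group").rename_axis("sample").to_csv(
            groups_path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"].to_dict()
        return cls(counts=counts, groups=groups)


def make_toy_model(
    n_linear_pathways: int = 12,
    genes_per_reaction: int = 1,
    chain_length: int = 3,
    uptake_bound: float = 10.0,
    subsystems: Sequence[str] | None = None,
    seed: int = 0,
) -> MetabolicModel:
    """Build a toy model of independent linear pathways with known optima.

    Pathway ``i``: uptake ``UPT_i`` (bounded ``[0, uptake_bound]``) produces
    ``m_i_0``; ``chain_length`` conversion reactions pass it along; a demand
    ``SINK_i`` drains the terminal metabolite. Pathway 1's terminal
    metabolite additionally feeds the ATP-maintenance pseudoreaction
    ``ATPM``. By construction, the maximal flux of every reaction in a
    pathway equals ``uptake_bound``; ATPM and SINK_1 share pathway 1's
    capacity (each can individually reach ``uptake_bound``). The ``seed``
    only affects nothing structural today and is kept for interface
    stability.
    """
    if n_linear_pathways < 1:
        raise ValueError("n_linear_pathways must be >= 1")
    if genes_per_reaction < 1:
        raise ValueError("genes_per_reaction must be >= 1")
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if subsystems is None:
        subsystems = [
            DEFAULT_SUBSYSTEMS[i % len(DEFAULT_SUBSYSTEMS)]
            if i < len(DEFAULT_SUBSYSTEMS)
            else f"Pathway {i + 1:02d}"
            for i in range(n_linear_pathways)
        ]
    if len(subsystems) != n_linear_pathways:
        raise ValueError("subsystems must have one label per pathway")

    def rule(pathway: int, role: str) -> str:
        gids = [f"g{pathway:02d}_{role}_{k}" for k in range(genes_per_reaction)]
        return " and ".join(gids)

    mets: list = []
    rxns: list = []
    for p in range(1, n_linear_pathways + 1):
        sub = subsystems[p - 1]
        for j in range(chain_length + 1):
            mets.append(Metabolite(f"m{p:02d}_{j}", compartment="c"))
        rxns.append(
            Reaction(
                id=f"UPT_{p:02d}",
                name=f"uptake, pathway {p}",
                subsystem=sub,
                lower_bound=0.0,
                upper_bound=uptake_bound,
                gpr=parse_gpr(rule(p, "u")),
                metabolites={f"m{p:02d}_0": 1.0},
            )
        )
        for j in range(1, chain_length + 1):
            rxns.append(
                Reaction(
                    id=f"CONV_{p:02d}_{j}",
                    name=f"conversion {j}, pathway {p}",
                    subsystem=sub,
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    gpr=parse_gpr(rule(p, f"c{j}of{chain_length}")),
                    metabolites={f"m{p:02d}_{j - 1}": -1.0, f"m{p:02d}_{j}": 1.0},
                )
            )
        rxns.append(
            Reaction(
                id=f"SINK_{p:02d}",
                name=f"demand, pathway {p}",
                subsystem=sub,
                lower_bound=0.0,
                upper_bound=1000.0,
                gpr=parse_gpr(rule(p, "s")),
                metabolites={f"m{p:02d}_{chain_length}": -1.0},
            )
        )
    rxns.append(
        Reaction(
            id="ATPM",
            name="ATP maintenance requirement",
            subsystem=ATPM_SUBSYSTEM,
            lower_bound=0.0,
            upper_bound=1000.0,
            metabolites={f"m01_{chain_length}": -1.0},
        )
    )
    return MetabolicModel(reactions=rxns, metabolites=mets, atpm_id="ATPM", id="toy")


def simulate_counts(model: MetabolicModel, design: SyntheticDesign) -> CountMatrix:
    """Draw NB counts for the model's genes under the synthetic design.

    Gene means are ``baseline_mean * 2**offset`` with the role offset encoded
    in the toy gene id (0 for foreign gene ids); genes attached to reactions
    of suppressed subsystems have their mean multiplied by
    ``2**suppression_lfc`` in the suppressed group only. Deterministic for a
    fixed seed.
    """
    known = set(model.subsystems)
    unknown = [s for s in design.suppressed_subsystems if s not in known]
    if unknown:
        raise ValueError(
            f"suppressed subsystem(s) {unknown} not in model; valid: {sorted(known)}"
        )

    genes: list = []
    suppressed_genes: set = set()
    for r in model.reactions:
        for g in sorted(r.gpr.genes):
            if g not in genes:
                genes.append(g)
            if r.subsystem in set(design.suppressed_subsystems):
                suppressed_genes.add(g)

    def offset(g: str) -> float:
        try:
            return gene_log2_offset(g)
        except ValueError:
            return 0.0

    base_mean = np.array([design.baseline_mean * 2.0 ** offset(g) for g in genes])
    supp = np.array([g in suppressed_genes for g in genes])
    factor = 2.0 ** design.suppression_lfc

    rng = np.random.default_rng(design.seed)
    nb_n = 1.0 / design.dispersion
    cols = {}
    for sample in design.samples:
        mean = base_mean.copy()
        if design.groups[sample] == design.suppressed_group:
            mean[supp] *= factor
        # NB(n, p) with mean m and variance m + dispersion*m^2
        p = nb_n / (nb_n + mean)
        cols[sample] = rng.negative_binomial(nb_n, p)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return CountMatrix(counts=counts, groups=design.groups)
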