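import numpy as np
import pandas as pd
import pytest

from fluxaging.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr
from fluxaging.synthetic_data import SyntheticDesign, make_toy_model, simulate_counts


@pytest.fixture(scope="session")
def toy_model():
    """Four-pathway toy model (21 reactions incl. ATPM)."""
    return make_toy_model(n_linear_pathways=4, seed=0)


@pytest.fixture(scope="session")
def toy_counts(toy_model):
    # suppress a strict subset of subsystems: size factors must be driven by
    # the unsuppressed majority, as in a transcriptome-scale matrix
    design = SyntheticDesign(
        seed=0, replicates=4, suppressed_subsystems=("Fatty acid oxidation",)
    )
    return simulate_counts(toy_model, design)


def linear_chain_model(intermediate_ub=1000.0):
    """uptake(<=10) -> A -> sink, with a tunable intermediate bound."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("UPT", lower_bound=0, upper_bound=10, metabolites={"A": 1}),
        Reaction("CONV", lower_bound=0, upper_bound=intermediate_ub,
                 metabolites={"A": -1, "B": 1}),
        Reaction("SINK", lower_bound=0, upper_bound=1000, metabolites={"B": -1}),
    ]
    return MetabolicModel(reactions=rxns, metabolites=mets)


def parallel_routes_model(cap1=3.0, cap2=5.0):
    """Two parallel routes into one sink (capacities cap1, cap2)."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("SRC", lower_bound=0, upper_bound=1000, metabolites={"A": 1}),
        Reaction("R1", lower_bound=0, upper_bound=cap1, metabolites={"A": -1, "B": 1}),
        Reaction("R2", lower_bound=0, upper_bound=cap2, metabolites={"A": -1, "B": 1}),
        Reaction("SINK", lower_bound=0, upper_bound=1000, metabolites={"B": -1}),
    ]
    return MetabolicModel(reactions=rxns, metabolites=mets)


def to_cobra(model):
    """Convert a MetabolicModel to a cobra.Model (test oracle only)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites([cobra.Metabolite(m.id, compartment=m.compartment or "c")
                        for m in model.metabolites])
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cm.metabolites.get_by_id(mid): coef for mid, coef in r.metabolites.items()}
        )
    return cm


def random_toy_model(rng):
    """Randomized multi-pathway toy model for oracle comparisons."""
    n_path = int(rng.integers(1, 4))
    chain = int(rng.integers(1, 4))
    model = make_toy_model(n_linear_pathways=n_path, chain_length=chain,
                           uptake_bound=float(rng.uniform(1, 20)), seed=0)
    # randomly tighten a few intermediate bounds
    for r in model.reactions:
        if r.id.startswith("CONV") and rng.random() < 0.4:
            r.upper_bound = float(rng.uniform(0.5, 15))
    return model
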