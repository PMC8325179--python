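from __future__ import annotations

import numpy as np
import pytest

from limogem.model import Metabolite, Model, Reaction
from limogem.synth import GroupSpec, NetworkSpec, PanelSpec, make_strain_panel, make_template_network


@pytest.fixture(scope="session")
def template_and_truth():
    return make_template_network(NetworkSpec(seed=11))


@pytest.fixture(scope="session")
def template_model(template_and_truth):
    return template_and_truth[0]


@pytest.fixture(scope="session")
def small_panel_and_truth(template_and_truth):
    """A reduced 4/4/2 host-group panel for unit tests (fast)."""
    template, truth = template_and_truth
    carb = {p: 1.0 for p in ("EMP", "PK", "lactate", "acetate", "ethanol")}
    base = dict(carb, folate=1.0, cobalamin=1.0, propanol=0.0)
    spec = PanelSpec(
        groups=[
            GroupSpec("herbivore", 4, dict(base, histamine=0.8, glycerol_3HPA_PDO=0.8)),
            GroupSpec("omnivore", 4, dict(base, histamine=0.5, glycerol_3HPA_PDO=0.5)),
            GroupSpec("sourdough", 2, dict(base, histamine=0.0, glycerol_3HPA_PDO=0.0)),
        ],
        auxotrophy_prob=0.25,
        seed=5,
    )
    return make_strain_panel(spec, template, truth)


@pytest.fixture()
def chain_model():
    """EX_A (lb=-10) -> A, A -> B, B -> (drain, objective); optimum 10."""
    m = Model(id="chain")
    m.add_metabolite(Metabolite("a_e", compartment="e"))
    m.add_metabolite(Metabolite("a_c", compartment="c"))
    m.add_metabolite(Metabolite("b_c", compartment="c"))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1}, lower_bound=-10, upper_bound=1000))
    m.add_reaction(Reaction("At", stoichiometry={"a_e": -1, "a_c": 1}, lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction("AB", stoichiometry={"a_c": -1, "b_c": 1}, lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction("BIO", stoichiometry={"b_c": -1}, lower_bound=0, upper_bound=1000))
    m.biomass_reaction_id = "BIO"
    m.objective_reaction_id = "BIO"
    return m


def model_from_arrays(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> Model:
    """Wrap a raw stoichiometric system as a Model (all-cytosolic)."""
    n_mets, n_rxns = S.shape
    m = Model(id="random")
    for i in range(n_mets):
        m.add_metabolite(Metabolite(f"m{i}_c", compartment="c"))
    for j in range(n_rxns):
        stoich = {f"m{i}_c": float(S[i, j]) for i in range(n_mets) if S[i, j] != 0}
        m.add_reaction(
            Reaction(f"r{j}", stoichiometry=stoich, lower_bound=float(lb[j]), upper_bound=float(ub[j]))
        )
    return m
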