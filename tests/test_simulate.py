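import copy

import numpy as np
import pytest

from limogem.errors import IntegrityError, MediumError, ValidationError
from limogem.media import AMINO_ACIDS, reference_medium
from limogem.model import Metabolite, Model, Reaction
from limogem.simulate import (
    PathwayCap,
    apply_medium,
    fba,
    growth_with_cap,
    omit_nutrient_screen,
    production_capability,
)
from limogem.synth import NetworkSpec, make_template_network

from _oracles import random_network, vertex_enumeration_max
from conftest import model_from_arrays


class TestFba:
    def test_linear_chain_optimum_is_uptake_limit(self, chain_model):
        sol = fba(chain_model, "BIO")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_no_input_no_growth(self, chain_model):
        sol = fba(chain_model, "BIO", extra_constraints={"EX_a_e": (0.0, 1000.0)})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_invalid_bounds_rejected_before_solve(self, chain_model):
        with pytest.raises(ValidationError):
            fba(chain_model, "BIO", extra_constraints={"AB": (1.0, -1.0)})

    def test_unknown_objective_is_integrity_error(self, chain_model):
        with pytest.raises(IntegrityError):
            fba(chain_model, "GHOST")

    def test_unbounded_reported_as_status(self):
        m = Model(id="ub")
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_reaction(Reaction("R1", stoichiometry={"a_c": 1}, lower_bound=-np.inf, upper_bound=np.inf))
        m.add_reaction(Reaction("R2", stoichiometry={"a_c": -1}, lower_bound=-np.inf, upper_bound=np.inf))
        sol = fba(m, "R1")
        assert sol.status == "unbounded"

    def test_steady_state_and_bounds_respected(self, template_model):
        model = apply_medium(template_model, reference_medium(glycerol=True))
        sol = fba(model, model.biomass_reaction_id)
        S = model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-6
        for rxn in model.reactions:
            assert rxn.lower_bound - 1e-6 <= sol.fluxes[rxn.id] <= rxn.upper_bound + 1e-6

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_vertex_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_rxns = int(rng.integers(3, 9))
        n_mets = int(rng.integers(2, 6))
        S, lb, ub, obj = random_network(rng, n_rxns, n_mets)
        model = model_from_arrays(S, lb, ub)
        sol = fba(model, f"r{obj}")
        c = np.zeros(n_rxns)
        c[obj] = 1.0
        expected = vertex_enumeration_max(S, lb, ub, c)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_lp_homogeneity_under_bound_scaling(self, chain_model):
        base = fba(chain_model, "BIO").objective_value
        for k in (0.5, 2.0, 7.5):
            scaled = chain_model.copy()
            for rxn in scaled.reactions:
                rxn.lower_bound *= k
                rxn.upper_bound *= k
            assert fba(scaled, "BIO").objective_value == pytest.approx(k * base, rel=1e-9)

    def test_agrees_with_cobra_on_template(self, tmp_path, template_model):
        cobra = pytest.importorskip("cobra")
        from cobra.io import read_sbml_model

        from limogem.io import write_model

        model = apply_medium(template_model, reference_medium(glycerol=True))
        path = tmp_path / "t.xml"
        write_model(model, path)
        cm = read_sbml_model(str(path))
        cm.objective = "BIOMASS"
        expected = cm.optimize().objective_value
        ours = fba(model, "BIOMASS").objective_value
        assert ours == pytest.approx(expected, rel=1e-6)


class TestMedium:
    def test_members_open_others_closed(self, template_model):
        model = apply_medium(template_model, {"glc_e": 25.0})
        assert model.exchange_for("glc_e").lower_bound == -25.0
        for rxn in model.exchanges():
            if "glc_e" not in rxn.stoichiometry:
                assert rxn.lower_bound == 0.0

    def test_second_medium_overrides_first(self, template_model):
        m1 = apply_medium(template_model, {"glc_e": 25.0})
        m2 = apply_medium(m1, {"ala_e": 5.0})
        assert m2.exchange_for("glc_e").lower_bound == 0.0
        assert m2.exchange_for("ala_e").lower_bound == -5.0

    def test_zero_rate_member_is_non_consumable(self, template_model):
        model = apply_medium(template_model, {"glc_e": 0.0})
        assert model.exchange_for("glc_e").lower_bound == 0.0

    def test_missing_exchange_raises_with_name(self, template_model):
        with pytest.raises(MediumError, match="unobtainium_e"):
            apply_medium(template_model, {"unobtainium_e": 1.0})


class TestCappedGrowth:
    def test_emp_cap_zero_leaves_pk_growth(self, template_model):
        med = reference_medium()
        uncapped = growth_with_cap(template_model, med)
        capped = growth_with_cap(template_model, med, PathwayCap(("PFK", "FBA"), 0.0))
        assert capped.grows
        assert capped.rate < uncapped.rate

    def test_infinite_cap_is_noop(self, template_model):
        med = reference_medium()
        uncapped = growth_with_cap(template_model, med)
        capped = growth_with_cap(template_model, med, PathwayCap(("PFK", "FBA"), np.inf))
        assert capped.rate == pytest.approx(uncapped.rate, rel=1e-9)

    def test_growth_monotone_in_cap(self, template_model):
        med = reference_medium()
        rates = [
            growth_with_cap(template_model, med, PathwayCap(("PFK", "FBA"), x)).rate
            for x in (0.0, 0.5, 1.0, 2.0, 5.0, 25.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(rates, rates[1:]))


class TestOmissionScreen:
    def test_planted_serine_auxotrophy_flagged_only(self):
        model, _ = make_template_network(NetworkSpec(seed=2, auxotrophies=("ser",)))
        verdicts = omit_nutrient_screen(
            model, reference_medium(), [f"{aa}_e" for aa in AMINO_ACIDS]
        )
        assert not verdicts["ser_e"].grows
        for aa in AMINO_ACIDS:
            if aa != "ser":
                assert verdicts[f"{aa}_e"].grows, aa

    def test_absent_nutrient_leaves_baseline(self, template_model):
        med = reference_medium()
        baseline = growth_with_cap(template_model, med)
        verdicts = omit_nutrient_screen(template_model, med, ["glyc_e"])
        assert verdicts["glyc_e"].rate == pytest.approx(baseline.rate, rel=1e-9)

    def test_model_untouched_after_screen(self, template_model):
        before = copy.deepcopy(
            [(r.id, r.lower_bound, r.upper_bound) for r in template_model.reactions]
        )
        omit_nutrient_screen(template_model, reference_medium(), ["ala_e", "gly_e"])
        after = [(r.id, r.lower_bound, r.upper_bound) for r in template_model.reactions]
        assert after == before


class TestCapability:
    def test_histamine_with_decarboxylase_and_histidine(self, template_model):
        capable, rate = production_capability(template_model, "hista_e", reference_medium())
        assert capable and rate > 0

    def test_absent_dehydratase_blocks_3hpa_and_pdo(self):
        spec = NetworkSpec(seed=4)
        spec.pathways["glycerol_3HPA_PDO"] = False
        model, _ = make_template_network(spec)
        assert not model.has_metabolite("13pdo_e")
        with pytest.raises(IntegrityError):
            production_capability(model, "13pdo_e", reference_medium())

    def test_capability_invariant_to_biomass_bounds(self, template_model):
        med = reference_medium()
        _, base_rate = production_capability(template_model, "lac_e", med)
        pinned = template_model.copy()
        bio = pinned.reaction(pinned.biomass_reaction_id)
        bio.lower_bound = 0.0
        bio.upper_bound = 0.0
        _, pinned_rate = production_capability(pinned, "lac_e", med)
        assert pinned_rate == pytest.approx(base_rate, rel=1e-6)

    def test_require_growth_flag_constrains(self, template_model):
        med = reference_medium()
        _, free_rate = production_capability(template_model, "lac_e", med)
        _, constrained = production_capability(template_model, "lac_e", med, require_growth=1.0)
        assert constrained <= free_rate + 1e-9
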