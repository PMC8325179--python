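import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limogem.errors import ConfigurationError, ReconciliationError
from limogem.gpr import parse_gpr
from limogem.media import MediumSpec
from limogem.model import Metabolite, Model, Reaction, reaction_signature
from limogem.reconstruct import (
    DNMP_MOLAR_MASS,
    BiomassSpec,
    add_exchanges_and_transport,
    assemble_biomass,
    build_draft,
    dna_biomass_coefficients,
    integrate_template,
)

from _oracles import gpr_truth


def tiny_template(gprs: dict[str, str]) -> Model:
    """One reaction per GPR string, all over a shared metabolite pool."""
    m = Model(id="tpl")
    m.add_metabolite(Metabolite("a_c", compartment="c"))
    m.add_metabolite(Metabolite("b_c", compartment="c"))
    genes = set()
    for text in gprs.values():
        genes |= parse_gpr(text).genes() if text else set()
    m.genes |= genes
    for rid, text in gprs.items():
        m.add_reaction(
            Reaction(rid, stoichiometry={"a_c": -1, "b_c": 1}, gpr=parse_gpr(text) if text else None)
        )
    return m


class TestBuildDraft:
    def test_and_gpr_fully_mapped_included_and_rewritten(self):
        tpl = tiny_template({"R1": "g1 and g2"})
        draft = build_draft(tpl, {"t1": "g1", "t2": "g2"})
        assert draft.has_reaction("R1")
        assert draft.reaction("R1").gpr == parse_gpr("t1 and t2")

    def test_or_gpr_partially_mapped_reduced_to_mapped_branch(self):
        tpl = tiny_template({"R1": "g1 or g2"})
        draft = build_draft(tpl, {"t1": "g1"})
        assert draft.reaction("R1").gpr == parse_gpr("t1")

    def test_and_gpr_partially_mapped_excluded(self):
        tpl = tiny_template({"R1": "g1 and g2"})
        assert not build_draft(tpl, {"t1": "g1"}).has_reaction("R1")

    def test_empty_map_keeps_only_spontaneous(self):
        tpl = tiny_template({"R1": "g1", "SPONT": ""})
        draft = build_draft(tpl, {})
        assert draft.reaction_ids == ["SPONT"]

    def test_exchanges_never_carried(self, template_model):
        draft = build_draft(template_model, {})
        assert not any(r.id.startswith("EX_") for r in draft.reactions)

    def test_included_set_equals_brute_force_gpr_evaluation(self, template_model):
        """Retention 0.6 draft equals independent per-reaction GPR truth."""
        rng = np.random.default_rng(42)
        genes = sorted(template_model.genes)
        retained = {g for g in genes if rng.random() < 0.6}
        ortholog_map = {f"ORG_{g}": g for g in retained}
        draft = build_draft(template_model, ortholog_map)
        from limogem.model import classify_reaction

        for rxn in template_model.reactions:
            if classify_reaction(rxn, template_model) == "exchange":
                expected = False
            elif rxn.gpr is None:
                expected = True
            else:
                expected = gpr_truth(rxn.gpr.to_string(), retained)
            assert draft.has_reaction(rxn.id) == expected, rxn.id


class TestIntegrate:
    def make_pair(self):
        tpl = tiny_template({"R1": "g1"})
        other = Model(id="tpl2")
        other.add_metabolite(Metabolite("a_c", compartment="c"))
        other.add_metabolite(Metabolite("b_c", compartment="c"))
        other.add_metabolite(Metabolite("c_c", compartment="c"))
        other.genes |= {"h1", "h2"}
        # same signature as R1, different id/GPR; plus a unique reaction
        other.add_reaction(Reaction("R1_dup", stoichiometry={"a_c": -1, "b_c": 1}, gpr=parse_gpr("h1")))
        other.add_reaction(Reaction("R2", stoichiometry={"b_c": -1, "c_c": 1}, gpr=parse_gpr("h2")))
        return tpl, other

    def test_duplicate_signature_not_added_unique_added(self):
        tpl, other = self.make_pair()
        draft = build_draft(tpl, {"t1": "g1"})
        merged = integrate_template(draft, other, {"t9": "h1", "t8": "h2"})
        assert not merged.has_reaction("R1_dup")
        assert merged.has_reaction("R2")
        assert merged.reaction("R2").gpr == parse_gpr("t8")

    def test_idempotent_reapplication(self):
        tpl, other = self.make_pair()
        draft = build_draft(tpl, {"t1": "g1"})
        once = integrate_template(draft, other, {"t8": "h2"})
        twice = integrate_template(once, other, {"t8": "h2"})
        assert twice.reaction_ids == once.reaction_ids

    def test_unsatisfied_gpr_not_integrated(self):
        tpl, other = self.make_pair()
        draft = build_draft(tpl, {"t1": "g1"})
        merged = integrate_template(draft, other, {})
        assert merged.reaction_ids == draft.reaction_ids

    def test_integration_is_monotone(self):
        tpl, other = self.make_pair()
        draft = build_draft(tpl, {"t1": "g1"})
        merged = integrate_template(draft, other, {"t8": "h2"})
        assert set(draft.reaction_ids) <= set(merged.reaction_ids)

    def test_conflicting_metabolite_definition_raises(self):
        tpl = tiny_template({"R1": "g1"})
        tpl.metabolite("a_c").formula = {"C": 6}
        tpl.metabolite("a_c").charge = 0
        other = Model(id="tpl2")
        other.add_metabolite(Metabolite("a_c", compartment="c", formula={"C": 5}, charge=0))
        other.add_metabolite(Metabolite("d_c", compartment="c"))
        other.genes.add("h1")
        other.add_reaction(Reaction("RX", stoichiometry={"a_c": -1, "d_c": 1}, gpr=parse_gpr("h1")))
        draft = build_draft(tpl, {"t1": "g1"})
        with pytest.raises(ReconciliationError):
            integrate_template(draft, other, {"t9": "h1"})


class TestExchangesAndTransport:
    def test_medium_member_gets_exchange_with_uptake_bound(self):
        m = Model(id="m")
        m.add_metabolite(Metabolite("glc_e", compartment="e"))
        out = add_exchanges_and_transport(m, MediumSpec("cdm", {"glc_e": 25.0}))
        ex = out.exchange_for("glc_e")
        assert (ex.lower_bound, ex.upper_bound) == (-25.0, 1000.0)

    def test_empty_medium_secretion_only(self, template_model):
        out = add_exchanges_and_transport(
            build_draft(template_model, {f"ORG_{g}": g for g in template_model.genes}),
            MediumSpec("none", {}),
        )
        for rxn in out.reactions:
            if rxn.id.startswith("EX_"):
                assert rxn.lower_bound == 0.0

    def test_transporter_copied_from_template(self, template_model):
        m = Model(id="m")
        medium = MediumSpec("g", {"glyc_e": 25.0})
        full_map = {f"ORG_{g}": g for g in template_model.genes}
        out = add_exchanges_and_transport(m, medium, [(template_model, full_map)])
        assert out.has_reaction("GLYCt")
        assert out.exchange_for("glyc_e").lower_bound == -25.0

    def test_diffusible_fallback_and_blocked_warning(self, caplog):
        m = Model(id="m")
        medium = MediumSpec("x", {"foo_e": 1.0, "bar_e": 1.0})
        with caplog.at_level("WARNING"):
            out = add_exchanges_and_transport(m, medium, diffusible={"foo_e"})
        assert out.has_reaction("FOOt_diff")
        assert not any("bar" in r.id and "diff" in r.id for r in out.reactions)
        assert any("bar_e" in rec.message for rec in caplog.records)


class TestDnaCoefficients:
    def test_gc_one_has_no_at(self):
        dna = dna_biomass_coefficients(1.0)
        assert dna.coefficients["damp"] == 0 and dna.coefficients["dtmp"] == 0
        assert dna.coefficients["dgmp"] == pytest.approx(dna.coefficients["dcmp"])
        mass = sum(dna.coefficients[n] * DNMP_MOLAR_MASS[n] for n in DNMP_MOLAR_MASS) / 1000
        assert mass == pytest.approx(0.031, abs=1e-12)

    def test_gc_half_symmetric(self):
        dna = dna_biomass_coefficients(0.5)
        values = set(round(v, 12) for v in dna.coefficients.values())
        # equal mole fractions but different molar masses: coefficients equal
        assert len({round(v, 15) for v in dna.coefficients.values()}) == 1
        assert dna.coefficients["damp"] == pytest.approx(dna.coefficients["dgmp"])

    def test_gc_039_matches_hand_computation(self):
        """Spreadsheet-style oracle at the fixture's typical GC content."""
        gc = 0.39
        x = {"damp": 0.305, "dtmp": 0.305, "dgmp": 0.195, "dcmp": 0.195}
        mean_mass = sum(x[n] * DNMP_MOLAR_MASS[n] for n in x)  # g/mol
        expected = {n: 1000 * x[n] * 0.031 / mean_mass for n in x}
        dna = dna_biomass_coefficients(gc)
        for n in expected:
            assert dna.coefficients[n] == pytest.approx(expected[n], rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(gc=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_mass_closure_for_any_gc(self, gc):
        dna = dna_biomass_coefficients(gc)
        mass = sum(dna.coefficients[n] * DNMP_MOLAR_MASS[n] for n in DNMP_MOLAR_MASS) / 1000
        assert mass == pytest.approx(0.031, abs=1e-12)

    @pytest.mark.parametrize("gc", [-0.1, 1.1])
    def test_domain_error(self, gc):
        with pytest.raises(ValueError):
            dna_biomass_coefficients(gc)


class TestAssembleBiomass:
    def spec(self):
        return BiomassSpec(
            source_template="tpl",
            classes={
                "protein": (0.55, {"ala_c": 0.2, "gly_c": 0.3}),
                "dna": (0.031, {}),
            },
        )

    def test_symmetric_dnmp_terms_at_gc_half(self):
        rxn = assemble_biomass(self.spec(), dna_biomass_coefficients(0.5))
        dnmp_terms = {m: c for m, c in rxn.stoichiometry.items() if m.startswith("d") and m.endswith("mp_c")}
        assert len(set(round(-c, 12) for c in dnmp_terms.values())) == 1
        assert rxn.stoichiometry["biomass_c"] == 1.0

    def test_protein_override_scales_only_protein(self):
        dna = dna_biomass_coefficients(0.5)
        base = assemble_biomass(self.spec(), dna)
        scaled = assemble_biomass(self.spec(), dna, overrides={"protein": 1.1})
        assert scaled.stoichiometry["ala_c"] == pytest.approx(1.1 * base.stoichiometry["ala_c"])
        assert scaled.stoichiometry["damp_c"] == base.stoichiometry["damp_c"]

    def test_unknown_override_class_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_biomass(self.spec(), dna_biomass_coefficients(0.5), overrides={"rna": 2.0})


def test_template_precedence_on_shared_signature(template_model):
    """The retained copy of a signature shared by several templates comes
    from the earliest template in the priority order."""
    full_map = {f"ORG_{g}": g for g in template_model.genes}
    draft = build_draft(template_model, full_map)
    # secondary template rewrites the same signature with other gene ids
    secondary = template_model.copy(new_id="secondary")
    for rxn in secondary.reactions:
        if rxn.gpr is not None:
            rxn.gpr = parse_gpr("ALT_gene")
    secondary.genes = {"ALT_gene"}
    merged = integrate_template(draft, secondary, {"t_alt": "ALT_gene"})
    sigs_draft = {reaction_signature(r) for r in draft.reactions}
    for rxn in merged.reactions:
        if reaction_signature(rxn) in sigs_draft and rxn.gpr is not None:
            assert "t_alt" not in {g for g in rxn.gpr.genes()}
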