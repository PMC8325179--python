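import numpy as np
import pytest

from limogem.errors import ValidationError
from limogem.model import Metabolite, Model, Reaction, reaction_signature
from limogem.pancore import (
    StrainPanel,
    classify_elements,
    core_model,
    element_key,
    group_summary,
    pan_model,
)

from _oracles import classify_by_membership


def set_model(mid: str, rxn_ids: list[str]) -> Model:
    """One irreversible single-metabolite-pair reaction per id; reaction
    identity then tracks the id under both identity modes."""
    m = Model(id=mid)
    for rid in rxn_ids:
        a, b = f"{rid}a_c", f"{rid}b_c"
        for met in (a, b):
            if not m.has_metabolite(met):
                m.add_metabolite(Metabolite(met, compartment="c"))
        m.add_reaction(Reaction(rid, stoichiometry={a: -1, b: 1}))
        m.genes.add(f"g_{rid}")
    return m


def key_set(model: Model) -> set:
    return {element_key(r, "reaction") for r in model.reactions}


class TestElementKey:
    def test_reversible_direction_normalized(self):
        r1 = Reaction("f", stoichiometry={"a_c": -1, "b_c": -1, "c_c": 1}, lower_bound=-10, upper_bound=10)
        r2 = Reaction("r", stoichiometry={"a_c": 1, "b_c": 1, "c_c": -1}, lower_bound=-10, upper_bound=10)
        assert element_key(r1, "reaction") == element_key(r2, "reaction")

    def test_gpr_not_part_of_identity(self):
        from limogem.gpr import parse_gpr

        r1 = Reaction("x", stoichiometry={"a_c": -1, "b_c": 1}, gpr=parse_gpr("g1"))
        r2 = Reaction("y", stoichiometry={"a_c": -1, "b_c": 1}, gpr=parse_gpr("g2 and g3"))
        assert element_key(r1, "reaction") == element_key(r2, "reaction")

    def test_distinct_key_count_equals_equivalence_classes(self, template_model):
        rxns = template_model.reactions
        keys = {element_key(r, "reaction") for r in rxns}
        # brute-force pairwise equivalence classes
        classes = []
        for r in rxns:
            for cls in classes:
                if reaction_signature(cls[0]) == reaction_signature(r):
                    cls.append(r)
                    break
            else:
                classes.append([r])
        assert len(keys) == len(classes)


class TestCorePan:
    def test_identical_models_core_is_model(self):
        a = set_model("a", ["r1", "r2"])
        b = set_model("b", ["r1", "r2"])
        core = core_model([a, b])
        assert key_set(core) == key_set(a)

    def test_simple_intersection(self):
        a = set_model("a", ["r1", "r2"])
        b = set_model("b", ["r1", "r3"])
        assert key_set(core_model([a, b])) == key_set(set_model("x", ["r1"]))

    def test_empty_intersection_is_valid_empty_model(self):
        core = core_model([set_model("a", ["r1"]), set_model("b", ["r2"])])
        assert core.reactions == []
        core.validate()

    def test_pan_of_disjoint_models_sums(self):
        a = set_model("a", ["r1", "r2"])
        b = set_model("b", ["r3"])
        assert len(pan_model([a, b]).reactions) == 3

    def test_pan_of_identical_models_is_model(self):
        a = set_model("a", ["r1", "r2"])
        assert key_set(pan_model([a, a.copy()])) == key_set(a)

    def test_containment_chain_on_random_panels(self):
        rng = np.random.default_rng(0)
        universe = [f"r{i}" for i in range(12)]
        for _ in range(25):
            models = [
                set_model(f"m{j}", [r for r in universe if rng.random() < 0.6])
                for j in range(int(rng.integers(2, 6)))
            ]
            models = [m for m in models if m.reactions]
            if len(models) < 2:
                continue
            core, pan = core_model(models), pan_model(models)
            for m in models:
                assert key_set(core) <= key_set(m) <= key_set(pan)

    def test_core_equals_brute_force_intersection(self, small_panel_and_truth):
        panel, _ = small_panel_and_truth
        core = core_model(panel.models)
        expected = set.intersection(*(key_set(m) for m in panel.models))
        assert key_set(core) == expected

    def test_order_invariance(self, small_panel_and_truth):
        panel, _ = small_panel_and_truth
        models = panel.models
        fwd_core = key_set(core_model(models))
        rev_core = key_set(core_model(models[::-1]))
        assert fwd_core == rev_core
        assert key_set(pan_model(models)) == key_set(pan_model(models[::-1]))


def panel_of(groups: dict[str, list[list[str]]]) -> StrainPanel:
    members = []
    for g, strain_sets in groups.items():
        for i, rxns in enumerate(strain_sets):
            members.append((f"{g}{i}", set_model(f"{g}{i}", rxns), g))
    return StrainPanel(members)


class TestClassification:
    def test_three_group_example_specific_and_common(self):
        panel = panel_of({"A": [["x", "y"]], "B": [["x", "z"]], "C": [["x"]]})
        cls = classify_elements(panel, "reaction", identity="id")
        assert cls.common == {"x"}
        assert cls.specific_all == {"y", "z"}
        assert cls.dispensable == set()

    def test_three_group_example_dispensable(self):
        panel = panel_of({"A": [["x", "w"]], "B": [["x", "w"]], "C": [["x"]]})
        cls = classify_elements(panel, "reaction", identity="id")
        assert cls.common == {"x"}
        assert cls.dispensable == {"w"}
        assert cls.specific_all == set()

    def test_single_group_is_error(self):
        panel = panel_of({"A": [["x"], ["y"]]})
        with pytest.raises(ValidationError):
            classify_elements(panel, "reaction")

    def test_two_groups_have_no_dispensable(self):
        panel = panel_of({"A": [["x", "y"]], "B": [["x", "z"]]})
        cls = classify_elements(panel, "reaction", identity="id")
        assert cls.dispensable == set()

    @pytest.mark.parametrize("kind", ["gene", "reaction", "metabolite"])
    def test_partition_sums_to_union(self, small_panel_and_truth, kind):
        panel, _ = small_panel_and_truth
        cls = classify_elements(panel, kind)
        assert len(cls.common) + len(cls.dispensable) + len(cls.specific_all) == cls.union_size

    def test_matches_brute_force_membership_counting(self):
        rng = np.random.default_rng(7)
        universe = [f"r{i}" for i in range(15)]
        for _ in range(20):
            groups = {
                g: [[r for r in universe if rng.random() < 0.5] or ["r0"]
                    for _ in range(int(rng.integers(1, 4)))]
                for g in ("A", "B", "C")
            }
            panel = panel_of(groups)
            cls = classify_elements(panel, "reaction", identity="id")
            group_sets = {
                g: set().union(*(set(s) for s in strain_sets))
                for g, strain_sets in groups.items()
            }
            common, dispensable, specific = classify_by_membership(group_sets)
            assert cls.common == common
            assert cls.dispensable == dispensable
            assert {g: s for g, s in cls.specific.items()} == specific


class TestGroupSummary:
    def test_single_strain_group_sd_zero_core_equals_pan(self):
        panel = panel_of({"A": [["x", "y"]], "B": [["x"], ["x", "z"]]})
        summary = group_summary(panel, identity="id")
        mean, sd = summary.sizes["A"]["reaction"]
        assert (mean, sd) == (2.0, 0.0)
        assert summary.core["A"]["reaction"] == summary.pan["A"]["reaction"] == 2

    def test_two_identical_strains(self):
        panel = panel_of({"A": [["x", "y"], ["x", "y"]], "B": [["x"]]})
        summary = group_summary(panel, identity="id")
        mean, sd = summary.sizes["A"]["reaction"]
        assert mean == 2.0 and sd == 0.0
        assert summary.core_pan_pct["A"]["reaction"] == 100.0

    def test_sample_sd_matches_independent_recomputation(self, small_panel_and_truth):
        panel, _ = small_panel_and_truth
        summary = group_summary(panel)
        for g in panel.groups:
            counts = [len(m.reactions) for m in panel.models_in(g)]
            assert summary.sizes[g]["reaction"][0] == pytest.approx(np.mean(counts))
            expected_sd = np.std(counts, ddof=1) if len(counts) > 1 else 0.0
            assert summary.sizes[g]["reaction"][1] == pytest.approx(expected_sd)

    def test_core_le_member_le_pan(self, small_panel_and_truth):
        panel, _ = small_panel_and_truth
        summary = group_summary(panel)
        for g in panel.groups:
            for m in panel.models_in(g):
                assert summary.core[g]["reaction"] <= len(m.reactions) <= summary.pan[g]["reaction"]
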