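"""PICO construction from text, structured records and knowledge rules."""

import pytest

from litcurate.fixtures import SCENARIO_TEXT
from litcurate.pico_builder import (
    KnowledgeRule,
    PicoQuestion,
    QueryType,
    Slot,
    WeightedTerm,
    assign_slot,
    identify_query_type,
    pico_from_rule,
    pico_from_structured,
    pico_from_text,
)
from litcurate.terminology import Concept, build_store


class TestPicoFromText:
    def test_worked_scenario(self, demo_store):
        q = pico_from_text(SCENARIO_TEXT, demo_store)
        p = {t.surface.lower() for t in q.p_terms}
        assert {"female", "blood pressure"} <= p
        ic = {t.surface.lower() for t in q.i_terms + q.c_terms}
        assert ic == {"beta-blocker", "ace inhibitor"}
        assert q.query_type is QueryType.TREATMENT

    def test_scenario_weights_follow_sti(self, demo_store):
        q = pico_from_text(SCENARIO_TEXT, demo_store)
        by_surface = {t.surface.lower(): t.weight for t in q.all_terms}
        assert by_surface["female"] == 1.0  # exact
        assert by_surface["ace inhibitor"] == 0.5  # synonym

    def test_stopword_only_text_is_unsearchable(self, demo_store):
        q = pico_from_text("the of and", demo_store)
        assert not q.searchable
        assert q.all_terms == []
        assert q.query_type is QueryType.UNKNOWN

    def test_single_population_term_goes_to_p(self, demo_store):
        q = pico_from_text("female", demo_store)
        assert [t.surface for t in q.p_terms] == ["female"]
        assert q.i_terms == q.c_terms == q.o_terms == []

    def test_empty_text_rejected(self, demo_store):
        with pytest.raises(ValueError):
            pico_from_text("", demo_store)

    def test_no_duplicate_surface_across_slots(self, demo_store):
        q = pico_from_text(SCENARIO_TEXT + " " + SCENARIO_TEXT, demo_store)
        surfaces = [t.surface.lower() for t in q.all_terms]
        assert len(surfaces) == len(set(surfaces))

    def test_repeated_mentions_slotted_once(self, demo_store):
        q = pico_from_text("female female female", demo_store)
        assert len(q.p_terms) == 1


class TestAssignSlot:
    def test_population_group_maps_to_p(self, demo_store):
        assert assign_slot(demo_store.get("C0001")) is Slot.P

    def test_first_drug_maps_to_i(self, demo_store):
        drug = demo_store.get("C0003")
        assert assign_slot(drug, intervention_seen=False) is Slot.I

    def test_second_drug_maps_to_c(self, demo_store):
        drug = demo_store.get("C0004")
        assert assign_slot(drug, intervention_seen=True) is Slot.C

    def test_unmapped_type_falls_back_to_p_with_warning(self):
        odd = Concept("X", "mystery", semantic_types=("unheard-of category",))
        with pytest.warns(UserWarning, match="no slot mapping"):
            assert assign_slot(odd) is Slot.P


class TestPicoFromRule:
    def test_rule_maps_data_action_purpose(self):
        rule = KnowledgeRule(
            data_elements=("hypertension",),
            action_elements=("beta-blocker", "ACE inhibitor"),
            purpose="lower blood pressure",
        )
        q = pico_from_rule(rule)
        assert [t.surface for t in q.p_terms] == ["hypertension"]
        assert [t.surface for t in q.i_terms] == ["beta-blocker"]
        assert [t.surface for t in q.c_terms] == ["ACE inhibitor"]
        assert [t.surface for t in q.o_terms] == ["lower blood pressure"]

    def test_production_rule_without_purpose_leaves_o_empty(self):
        rule = KnowledgeRule(data_elements=("hypertension",), action_elements=("statin",))
        assert pico_from_rule(rule).o_terms == []

    def test_empty_data_elements_rejected(self):
        rule = KnowledgeRule(data_elements=(), action_elements=("x",))
        with pytest.raises(ValueError):
            pico_from_rule(rule)

    def test_data_element_order_does_not_change_p_set(self):
        a = pico_from_rule(KnowledgeRule(data_elements=("x", "y", "z")))
        b = pico_from_rule(KnowledgeRule(data_elements=("z", "x", "y")))
        key = lambda q: {t.surface for t in q.p_terms}
        assert key(a) == key(b)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            KnowledgeRule(data_elements=("x",), scheme="prolog")


class TestStructuredRecord:
    def test_labeled_slots_pass_through(self, demo_store):
        q = pico_from_structured(
            {"problem": ["female"], "intervention": ["beta-blocker"]},
            demo_store,
        )
        assert [t.surface for t in q.p_terms] == ["female"]
        assert [t.surface for t in q.i_terms] == ["beta-blocker"]
        # STI standardization attached concept ids
        assert q.p_terms[0].concept_id == "C0001"

    def test_works_without_a_store(self):
        q = pico_from_structured({"outcome": ["mortality"]})
        assert [t.surface for t in q.o_terms] == ["mortality"]


def _question_with(*terms):
    q = PicoQuestion()
    for t in terms:
        q.add(t)
    return q


class TestQueryType:
    def test_two_treatment_parents_vote_treatment(self, demo_store):
        q = _question_with(
            WeightedTerm("beta-blocker", "C0003", 1.0, Slot.I),
            WeightedTerm("ACE inhibitor", "C0004", 0.5, Slot.C),
        )
        assert identify_query_type(q, demo_store) is QueryType.TREATMENT

    def test_empty_intervention_slots_give_unknown(self, demo_store):
        q = _question_with(WeightedTerm("female", "C0001", 1.0, Slot.P))
        assert identify_query_type(q, demo_store) is QueryType.UNKNOWN

    def test_majority_vote(self):
        store = build_store(
            [
                Concept("T", "antihypertensive agent"),
                Concept("D", "diagnostic procedure"),
                Concept("a", "drug a", parent_ids=("T",)),
                Concept("b", "drug b", parent_ids=("T",)),
                Concept("c", "scan c", parent_ids=("D",)),
            ]
        )
        q = _question_with(
            WeightedTerm("drug a", "a", 1.0, Slot.I),
            WeightedTerm("drug b", "b", 1.0, Slot.C),
            WeightedTerm("scan c", "c", 1.0, Slot.C),
        )
        assert identify_query_type(q, store) is QueryType.TREATMENT

    def test_tie_resolves_by_fixed_priority(self):
        store = build_store(
            [
                Concept("T", "antihypertensive agent"),
                Concept("D", "diagnostic procedure"),
                Concept("a", "drug a", parent_ids=("T",)),
                Concept("c", "scan c", parent_ids=("D",)),
            ]
        )
        q = _question_with(
            WeightedTerm("drug a", "a", 1.0, Slot.I),
            WeightedTerm("scan c", "c", 1.0, Slot.C),
        )
        assert identify_query_type(q, store) is QueryType.TREATMENT

    def test_adding_majority_concept_never_flips_result(self):
        """Majority vote is monotone in votes for the current winner."""
        store = build_store(
            [
                Concept("T", "antihypertensive agent"),
                Concept("D", "diagnostic procedure"),
                Concept("a", "drug a", parent_ids=("T",)),
                Concept("b", "drug b", parent_ids=("T",)),
                Concept("c", "scan c", parent_ids=("D",)),
            ]
        )
        base = [
            WeightedTerm("drug a", "a", 1.0, Slot.I),
            WeightedTerm("scan c", "c", 1.0, Slot.C),
        ]
        before = identify_query_type(_question_with(*base), store)
        after = identify_query_type(
            _question_with(*base, WeightedTerm("drug b", "b", 1.0, Slot.C)), store
        )
        assert before is QueryType.TREATMENT and after is QueryType.TREATMENT
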