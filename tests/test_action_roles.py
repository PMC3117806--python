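import pytest

from chemphrase.action_roles import (
    ActionType,
    all_actions,
    build_reaction_graph,
    extract_reference_number,
    graph_to_tsv,
    identify_actions,
    summarize_preparation,
)
from chemphrase.pipeline import parse_document
from chemphrase.samples import ACTION_EXAMPLES, PREPARATION


class TestIdentifyActions:
    def test_heat_example(self):
        doc = parse_document("The mixture was heated under reflux for 8 h.")
        assert [a.type for a in doc.actions] == [ActionType.Heat]

    def test_add_phrase_wraps_whole_sentence(self, sample_doc):
        assert len(sample_doc.actions) == 1
        action = sample_doc.actions[0]
        assert action.type is ActionType.Add
        # the wrapped subtree carries every token of the sentence
        assert action.node.leaf_tokens() == sample_doc.segments[0]

    def test_pure_narration_yields_nothing(self):
        doc = parse_document("The results are shown below.")
        assert doc.actions == []

    def test_trigger_inside_prep_phrase_is_not_an_action(self):
        doc = parse_document(
            "The filtrate was concentrated under reduced pressure without heating."
        )
        assert [a.type for a in doc.actions] == [ActionType.Concentrate]

    def test_nested_implicit_dissolve_in_preparation(self, prep_doc):
        add = prep_doc.actions[0]
        assert add.type is ActionType.Add
        assert [n.type for n in add.nested] == [ActionType.Dissolve]
        start, end = add.nested[0].span
        outer_start, outer_end = add.span
        assert outer_start <= start < end <= outer_end

    def test_sibling_actions_do_not_overlap(self, prep_doc):
        for tree in prep_doc.sentences:
            spans = [
                node.span()
                for node in tree.children
                if node.label == "ActionPhrase"
            ]
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestTable1Conformance:
    @pytest.mark.parametrize("family", sorted(ACTION_EXAMPLES))
    def test_each_example_classifies_to_its_family(self, family):
        doc = parse_document(ACTION_EXAMPLES[family])
        types = [a.type.name for a in doc.actions]
        assert types, f"no action found in {family} example"
        assert types[0] == family

    def test_registry_has_exactly_21_types(self):
        assert len(ActionType) == 21
        assert set(ACTION_EXAMPLES) == {t.name for t in ActionType}


class TestRoles:
    def role_of(self, doc, fragment):
        for r in doc.roles:
            if fragment in r.surface:
                return r.role
        raise AssertionError(f"no molecule matching {fragment!r}")

    def test_worked_preparation_roles(self, prep_doc):
        assert self.role_of(prep_doc, "N-dimethylformamide") == "solvent"
        assert self.role_of(prep_doc, "2-nitrobenzene sulfonamide") == "reactant"
        assert self.role_of(prep_doc, "benzazepine") == "product"

    def test_wash_with_brine_marks_solvent(self):
        doc = parse_document(
            "The combined organic extracts were washed with brine."
        )
        assert [a.type for a in doc.actions] == [ActionType.Wash]
        (role,) = [r for r in doc.roles if "brine" in r.surface]
        assert role.role == "solvent"

    def test_no_actions_means_all_unassigned(self):
        doc = parse_document("thiophenol and methanol")
        assert doc.actions == []
        assert {r.role for r in doc.roles} == {"unassigned"}

    def test_at_most_one_role_per_molecule(self, prep_doc):
        seen = set()
        for r in prep_doc.roles:
            assert id(r.molecule) not in seen
            seen.add(id(r.molecule))


class TestReferenceNumbers:
    def test_title_line_reference(self, prep_doc):
        assert extract_reference_number(prep_doc.title) == 82

    def test_reactant_reference(self, prep_doc):
        (reactant,) = [r for r in prep_doc.roles if r.role == "reactant"]
        assert extract_reference_number(reactant.molecule) == 50

    def test_absent_reference(self):
        doc = parse_document("thiophenol was added.")
        mol = doc.sentences[0].find("MOLECULE")[0]
        assert extract_reference_number(mol) is None


class TestReactionGraph:
    def test_worked_preparation_graph(self, prep_doc):
        graph = build_reaction_graph([prep_doc])
        assert set(graph.nodes) == {50, 82}
        assert list(graph.edges) == [(50, 82)]
        assert graph.nodes[82]["state"] == "oil"

    def test_empty_document_list(self):
        graph = build_reaction_graph([])
        assert graph.number_of_nodes() == 0

    def test_shared_reactant_has_out_degree_two(self):
        first = (
            "Product alpha 7:\n"
            "The 2-nitrobenzene sulfonamide 5 (0.50 g, 1.3 mmol) was added "
            "to the solution and stirred for 2 h. Chromatography afforded "
            "the title compound 7 as a white solid (88 mg, 70%)."
        )
        second = (
            "Product beta 9:\n"
            "The 2-nitrobenzene sulfonamide 5 (0.25 g, 0.65 mmol) was "
            "added to the solution and stirred for 4 h. Chromatography "
            "afforded the title compound 9 as a yellow oil (40 mg, 55%)."
        )
        docs = [parse_document(t) for t in (first, second)]
        graph = build_reaction_graph(docs)
        assert graph.out_degree(5) == 2
        assert set(graph.successors(5)) == {7, 9}
        assert graph.nodes[9]["state"] == "oil"
        assert graph.nodes[9]["colour"] == "yellow"

    def test_tsv_export(self, prep_doc):
        nodes_tsv, edges_tsv = graph_to_tsv(build_reaction_graph([prep_doc]))
        assert "82\toil" in nodes_tsv
        assert "50\t82" in edges_tsv


def test_summary_of_preparation(prep_doc):
    summary = summarize_preparation(
        prep_doc.sentences, prep_doc.actions, prep_doc.roles,
        title=prep_doc.title,
    )
    assert summary.product_ref == 82
    assert summary.reactant_refs == [50]
    assert summary.product_state == "oil"


def test_all_actions_flattens_nesting(prep_doc):
    flat = all_actions(prep_doc.actions)
    assert len(flat) == len(prep_doc.actions) + sum(
        len(a.nested) for a in prep_doc.actions
    )
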