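"""Action-phrase labelling and compound-role inference.

A parsed sentence is scanned for verbs (or nominalisations) belonging to
one of 21 closed action families — the procedural steps of a synthesis
(Add, Stir, Heat, Yield, ...).  The matching subtrees are wrapped in
``ActionPhrase`` nodes; an implicit "X in solvent" pattern inside another
action is additionally wrapped as a nested Dissolve phrase.

Roles (solvent / reactant / product) are then inferred from linguistic
context: solvents sit after "in"/"with" prepositions inside dissolution-
like actions; reactants carry a compound-reference number near the start
of the preparation; the product is the title-line compound, corroborated
by the Yield phrase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .phrase_parser import PhraseNode
from .taggers import ACTION_FAMILIES, verb_tag_to_family

__all__ = [
    "ActionType",
    "ActionPhrase",
    "RoleAssignment",
    "PreparationSummary",
    "identify_actions",
    "all_actions",
    "assign_roles",
    "extract_reference_number",
    "summarize_preparation",
    "build_reaction_graph",
    "graph_to_tsv",
]

log = logging.getLogger(__name__)

ActionType = Enum("ActionType", {name: name for name in ACTION_FAMILIES})
ActionType.__doc__ = "The closed set of 21 procedural action families."

#: Action types whose in/with prepositional complements name solvents.
SOLVENT_ACTIONS = frozenset({"Dissolve", "Wash", "Extract", "Quench", "Partition"})
SOLVENT_PREPOSITIONS = frozenset({"in", "with"})

_STATES = {
    "oil": "oil", "oils": "oil", "solid": "solid", "solids": "solid",
    "gum": "gum", "foam": "foam", "foams": "foam", "crystal": "crystals",
    "crystals": "crystals", "needle": "crystals", "needles": "crystals",
}
_COLOURS = frozenset(
    "white yellow colourless colorless red brown pale dark orange green".split()
)


@dataclass
class ActionPhrase:
    """One labelled procedural step, backed by a subtree of the parse."""

    type: ActionType
    node: PhraseNode
    span: tuple[int, int]
    nested: list["ActionPhrase"] = field(default_factory=list)

    @property
    def surface(self) -> str:
        return self.node.surface()


@dataclass
class RoleAssignment:
    molecule: PhraseNode
    role: str  # solvent | reactant | product | unassigned
    evidence: str = ""

    @property
    def surface(self) -> str:
        return self.molecule.surface()


def _trigger_family(vp: PhraseNode) -> str | None:
    """Action family of a verb phrase's first action verb, if any.

    Only direct leaf children count: a trigger inside a prepositional
    complement ("without heating", "under stirring") names a condition,
    not a step.
    """
    for child in vp.children:
        if child.is_leaf:
            family = verb_tag_to_family(child.label)
            if family is not None:
                return family
    return None


def _is_participial(vp: PhraseNode) -> bool:
    """True for a bare participle phrase: no finite auxiliary, no "to"."""
    for child in vp.children:
        if child.is_leaf and child.label in {"VBD", "VB", "TO"}:
            return False
    return True


def _contains_molecule(node: PhraseNode) -> bool:
    return bool(node.find("MOLECULE"))


def _wrap_implicit_dissolve(action: "ActionPhrase") -> None:
    """Wrap "MOLECULE ... in MOLECULE(quantity)" pairs as nested Dissolve.

    The pattern "the sulfonamide 50 (...) in N,N-dimethylformamide (33
    cm3)" describes a solution even without a dissolve verb; the solvent
    sits in the "in" prepositional phrase.
    """
    if action.type is ActionType.Dissolve:
        return

    def visit(node: PhraseNode) -> None:
        if node.is_leaf:
            return
        i = 1
        while i < len(node.children):
            prev, cur = node.children[i - 1], node.children[i]
            if (
                cur.label == "PrepPhrase"
                and cur.children
                and cur.children[0].is_leaf
                and cur.children[0].token.surface.lower() == "in"
                and _contains_molecule(cur)
                and prev.label in {"NounPhrase", "PrepPhrase", "MOLECULE"}
                and _contains_molecule(prev)
                and prev.label != "ActionPhrase"
            ):
                wrapper = PhraseNode(
                    "ActionPhrase",
                    children=[prev, cur],
                    attributes={"type": ActionType.Dissolve.name},
                )
                node.children[i - 1 : i + 1] = [wrapper]
                action.nested.append(
                    ActionPhrase(ActionType.Dissolve, wrapper, wrapper.span())
                )
                continue
            visit(cur)
            i += 1
        if node.children:
            visit(node.children[0])

    visit(action.node)


def identify_actions(sentence: PhraseNode) -> list[ActionPhrase]:
    """Wrap action-bearing stretches of a parsed sentence in ActionPhrases.

    The sentence tree is restructured in place: each verb phrase whose
    verb maps to an action family opens an ``ActionPhrase`` node that
    absorbs its subject noun phrase and everything up to the next
    conjunction or trigger.  A participial trigger occurring inside an
    open action becomes a nested phrase rather than a sibling.  Sentences
    without triggers are left untouched and yield ``[]``.
    """
    actions: list[ActionPhrase] = []
    new_children: list[PhraseNode] = []
    current: ActionPhrase | None = None

    for child in sentence.children:
        if child.is_leaf and child.label == "CC":
            current = None
            new_children.append(child)
            continue
        if child.label == "VerbPhrase":
            family = _trigger_family(child)
            if family is not None:
                if current is not None and _is_participial(child):
                    # e.g. "... a solution of X dissolved in Y"
                    wrapper = PhraseNode(
                        "ActionPhrase",
                        children=[child],
                        attributes={"type": family},
                    )
                    current.node.children.append(wrapper)
                    current.nested.append(
                        ActionPhrase(ActionType[family], wrapper, wrapper.span())
                    )
                    continue
                wrapper = PhraseNode(
                    "ActionPhrase", attributes={"type": family}
                )
                if new_children and new_children[-1].label == "NounPhrase":
                    wrapper.children.append(new_children.pop())
                wrapper.children.append(child)
                new_children.append(wrapper)
                current = ActionPhrase(ActionType[family], wrapper, (0, 0))
                actions.append(current)
                continue
        if current is not None:
            current.node.children.append(child)
        else:
            new_children.append(child)

    sentence.children = new_children
    for action in actions:
        _wrap_implicit_dissolve(action)
        action.span = action.node.span()
        for nested in action.nested:
            nested.span = nested.node.span()
    return actions


def all_actions(actions: list[ActionPhrase]) -> list[ActionPhrase]:
    """Flatten an action list, nested phrases included."""
    out: list[ActionPhrase] = []
    for a in actions:
        out.append(a)
        out.extend(all_actions(a.nested))
    return out


def extract_reference_number(node: PhraseNode) -> int | None:
    """The compound-reference integer attached to a molecule or title line.

    Accepts any bold dialect (``**82**``, ``<b>82</b>``, positional); a
    title line may also end "... 82 :" with the number as a plain
    cardinal before the colon.  Returns ``None`` when absent.
    """
    leaves = node.leaves()
    for leaf in leaves:
        if leaf.label == "CD-BOLD":
            digits = "".join(c for c in leaf.token.surface if c.isdigit())
            if digits:
                return int(digits)
    for i, leaf in enumerate(leaves[:-1]):
        if leaf.label == "CD" and leaves[i + 1].label == "COLON":
            return int(float(leaf.token.surface))
    return None


def _molecules_in_order(nodes: list[PhraseNode]) -> list[PhraseNode]:
    out: list[PhraseNode] = []
    for node in nodes:
        out.extend(node.find("MOLECULE"))
    return out


def assign_roles(
    sentences: list[PhraseNode],
    actions: list[ActionPhrase],
    *,
    title: PhraseNode | None = None,
    solvent_actions: frozenset[str] = SOLVENT_ACTIONS,
) -> list[RoleAssignment]:
    """Infer solvent / reactant / product roles for molecule occurrences.

    Rule precedence (strongest first):

    * product — the title-line compound; also a referenced molecule
      inside a Yield phrase;
    * solvent — a molecule inside an "in"/"with" prepositional phrase
      within a dissolution-like action (Dissolve, Wash, Extract, Quench,
      Partition — configurable), nested implicit Dissolve included;
    * reactant — a molecule carrying a compound-reference number within
      the first two sentences.

    Everything else is reported as ``unassigned``.
    """
    scope = ([title] if title is not None else []) + list(sentences)
    molecules = _molecules_in_order(scope)
    roles: dict[int, RoleAssignment] = {}

    def assign(mol: PhraseNode, role: str, evidence: str) -> None:
        roles.setdefault(id(mol), RoleAssignment(mol, role, evidence))

    flat = all_actions(actions)

    # product: title compound ...
    if title is not None:
        for mol in title.find("MOLECULE"):
            ref = extract_reference_number(title)
            corroborated = any(
                a.type is ActionType.Yield
                and extract_reference_number(a.node) == ref
                for a in flat
            )
            evidence = "title"
            if ref is not None:
                evidence += f":ref={ref}"
            if corroborated:
                evidence += ":yield-corroborated"
            assign(mol, "product", evidence)
    # ... and referenced molecules inside Yield phrases
    for action in flat:
        if action.type is ActionType.Yield:
            for mol in action.node.find("MOLECULE"):
                if extract_reference_number(mol) is not None:
                    assign(mol, "product", "yield-phrase")

    # solvent
    for action in flat:
        if action.type.name not in solvent_actions and action.type is not ActionType.Dissolve:
            continue
        for pp in action.node.find("PrepPhrase"):
            head = pp.children[0] if pp.children else None
            if (
                head is None
                or not head.is_leaf
                or head.token.surface.lower() not in SOLVENT_PREPOSITIONS
            ):
                continue
            for mol in pp.find("MOLECULE"):
                assign(mol, "solvent", f"solvent:{action.type.name}/{head.token.surface.lower()}")

    # reactant
    early = _molecules_in_order(list(sentences)[:2])
    for mol in early:
        if extract_reference_number(mol) is not None:
            assign(mol, "reactant", "start-of-text:referenced")

    out: list[RoleAssignment] = []
    for mol in molecules:
        out.append(roles.get(id(mol), RoleAssignment(mol, "unassigned")))
    return out


@dataclass
class PreparationSummary:
    """What a reaction graph needs to know about one preparation."""

    product_ref: int | None
    reactant_refs: list[int]
    product_state: str = "unknown"
    product_colour: str | None = None
    source_id: str = ""


def _yield_state_colour(action: ActionPhrase) -> tuple[str, str | None]:
    state, colour = "unknown", None
    for pp in action.node.find("PrepPhrase"):
        head = pp.children[0] if pp.children else None
        if head is None or not head.is_leaf or head.token.surface.lower() != "as":
            continue
        leaves = pp.leaves()
        for i, leaf in enumerate(leaves):
            word = leaf.token.surface.lower()
            if word in _STATES:
                state = _STATES[word]
                for prev in reversed(leaves[:i]):
                    if prev.token.surface.lower() in _COLOURS:
                        colour = prev.token.surface.lower()
                        break
                return state, colour
    return state, colour


def summarize_preparation(
    sentences: list[PhraseNode],
    actions: list[ActionPhrase],
    roles: list[RoleAssignment],
    *,
    title: PhraseNode | None = None,
    source_id: str = "",
) -> PreparationSummary:
    """Condense one parsed preparation into graph-ready facts."""
    flat = all_actions(actions)
    product_ref: int | None = None
    if title is not None:
        product_ref = extract_reference_number(title)
    state, colour = "unknown", None
    for action in flat:
        if action.type is ActionType.Yield:
            if product_ref is None:
                product_ref = extract_reference_number(action.node)
            state, colour = _yield_state_colour(action)
            break
    reactant_refs: list[int] = []
    for role in roles:
        if role.role == "reactant":
            ref = extract_reference_number(role.molecule)
            if ref is not None and ref not in reactant_refs:
                reactant_refs.append(ref)
    return PreparationSummary(product_ref, reactant_refs, state, colour, source_id)


def build_reaction_graph(documents: list) -> nx.DiGraph:
    """Assemble the reactant→product graph across preparations.

    ``documents`` are :class:`PreparationSummary` objects or anything with
    the same attributes (parsed documents expose one via ``.summary``).
    Nodes are compound-reference numbers; node attributes record the
    product's physical state and colour where extracted.  A preparation
    without a product contributes no edges (a warning is logged).
    """
    graph = nx.DiGraph()
    for doc in documents:
        summary = getattr(doc, "summary", doc)
        for ref in summary.reactant_refs:
            if ref not in graph:
                graph.add_node(ref, state="unknown", colour="")
        if summary.product_ref is None:
            if summary.reactant_refs:
                log.warning(
                    "preparation %r has reactants but no product; edges omitted",
                    summary.source_id,
                )
            continue
        graph.add_node(
            summary.product_ref,
            state=summary.product_state,
            colour=summary.product_colour or "",
        )
        for ref in summary.reactant_refs:
            graph.add_edge(ref, summary.product_ref)
    return graph


def graph_to_tsv(graph: nx.DiGraph) -> tuple[str, str]:
    """Tab-separated node and edge lists for a reaction graph."""
    nodes = ["id\tstate\tcolour"]
    for n, data in sorted(graph.nodes(data=True)):
        nodes.append(f"{n}\t{data.get('state', 'unknown')}\t{data.get('colour') or ''}")
    edges = ["reactant\tproduct"]
    for u, v in sorted(graph.edges()):
        edges.append(f"{u}\t{v}")
    return "\n".join(nodes) + "\n", "\n".join(edges) + "\n"
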