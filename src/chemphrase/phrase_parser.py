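"""Deterministic phrase parsing of tagged sentences into a phrase tree.

Experimental chemistry prose is formulaic enough that a small formal
grammar yields (almost always) a single parse.  The parser here is a
recursive-descent / ordered-choice parser with unbounded lookahead and
backtracking over the tag sequence.  The core productions are:

    sentence    : (nounphrase | verbphrase | prepphrase | ...)*
    nounphrase  : DT? modifier* nounitem ((CC|COMMA) nounitem)*
    nounitem    : molecule | noun+ reference? quantity?
    molecule    : OSCAR+ reference? quantity?
    quantity    : LRB amount (COMMA amount)* RRB
    verbphrase  : TO? adv* verb+ (prepphrase | nounphrase | ...)*
    prepphrase  : (IN|TO) (nounphrase | gerund)

Token subsequences that match no production are wrapped in ``Unmatched``
nodes rather than aborting: parsing degrades, it never raises.  Every
input token appears exactly once among the leaves of the returned tree
(the leaf-partition invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .taggers import TaggedToken, UNIT_TAGS

__all__ = [
    "PhraseNode",
    "Quantity",
    "parse_sentence",
    "parse_quantity",
    "ast_leaf_tokens",
]

PHRASE_LABELS = frozenset(
    {
        "Sentence",
        "ActionPhrase",
        "NounPhrase",
        "VerbPhrase",
        "PrepPhrase",
        "MOLECULE",
        "QUANTITY",
        "Unmatched",
    }
)


@dataclass
class PhraseNode:
    """A node of the phrase tree.

    Internal nodes carry a label from :data:`PHRASE_LABELS`; leaves carry
    exactly one tagged token and use the token's tag as their label.
    Structural equality ignores character offsets (XML round trips
    preserve structure and surfaces, not offsets).
    """

    label: str
    children: list["PhraseNode"] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)
    token: TaggedToken | None = None

    @classmethod
    def leaf(cls, tt: TaggedToken) -> "PhraseNode":
        return cls(label=tt.tag, token=tt)

    @property
    def is_leaf(self) -> bool:
        return self.token is not None

    def leaves(self) -> list["PhraseNode"]:
        if self.is_leaf:
            return [self]
        out: list[PhraseNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_tokens(self) -> list[TaggedToken]:
        return [leaf.token for leaf in self.leaves()]

    def surface(self) -> str:
        return " ".join(tt.surface for tt in self.leaf_tokens())

    def span(self) -> tuple[int, int]:
        """Character span over the raw text (0-based, half-open)."""
        toks = self.leaf_tokens()
        if not toks:
            return (0, 0)
        return toks[0].token.start, toks[-1].token.end

    def find(self, label: str) -> list["PhraseNode"]:
        """All descendant nodes (including self) with the given label."""
        out = [self] if self.label == label else []
        for child in self.children:
            out.extend(child.find(label))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhraseNode):
            return NotImplemented
        if self.label != other.label or self.attributes != other.attributes:
            return False
        if self.is_leaf or other.is_leaf:
            return (
                self.is_leaf
                and other.is_leaf
                and self.token.surface == other.token.surface
                and self.token.tag == other.token.tag
            )
        return self.children == other.children


@dataclass(frozen=True)
class Quantity:
    """A typed physical amount from a bracketed data phrase."""

    kind: str  # mass|molar|volume|percent|temperature|time|equivalents|unknown
    value: float
    unit: str = ""
    qualifier: str | None = None
    repeat: int | None = None


_UNIT_KIND = {
    "NN-MASS": "mass",
    "NN-MOLAR": "molar",
    "NN-VOL": "volume",
    "NN-PERCENT": "percent",
    "NN-TEMP": "temperature",
    "NN-TIME": "time",
    "NN-EQUIV": "equivalents",
}

NOUN_TAGS = frozenset(
    {
        "NN",
        "NNS",
        "NNP",
        "NN-STATE",
        "NN-MIXTURE",
        "NN-SOLUTION",
        "NN-TIME",
        "NN-TEMP",
        "NN-VOL",
        "NN-MASS",
        "NN-MOLAR",
        "NN-EQUIV",
    }
)
MODIFIER_TAGS = frozenset({"JJ", "CD"})
_AUX = frozenset("was were is are be been being has have had".split())
#: Tokens allowed inside a bracketed quantity group.
_QTY_TAGS = frozenset({"CD", "COMMA", "RB", "TIMES", "CD-BOLD"}) | UNIT_TAGS


class _Parser:
    def __init__(self, tagged: list[TaggedToken]):
        self.toks = tagged
        self.i = 0

    # -- cursor helpers -------------------------------------------------
    def tag(self, k: int = 0) -> str | None:
        j = self.i + k
        return self.toks[j].tag if j < len(self.toks) else None

    def take(self) -> PhraseNode:
        node = PhraseNode.leaf(self.toks[self.i])
        self.i += 1
        return node

    def at_end(self) -> bool:
        return self.i >= len(self.toks)

    # -- productions ----------------------------------------------------
    def p_sentence(self) -> PhraseNode:
        children: list[PhraseNode] = []
        pending: list[PhraseNode] = []

        def flush() -> None:
            if pending:
                children.append(PhraseNode("Unmatched", children=list(pending)))
                pending.clear()

        while not self.at_end():
            node = (
                self.p_nounphrase()
                or self.p_verbphrase()
                or self.p_prepphrase()
                or self.p_quantity_group()
                or self.p_parenthetical()
            )
            if node is not None:
                flush()
                children.append(node)
            elif self.tag() in {"CC", "STOP", "COLON", "COMMA", "SEMICOLON"}:
                flush()
                children.append(self.take())
            else:
                pending.append(self.take())
        flush()
        return PhraseNode("Sentence", children=children)

    def p_nounphrase(self) -> PhraseNode | None:
        start = self.i
        children: list[PhraseNode] = []
        if self.tag() == "DT":
            children.append(self.take())
        while True:
            t = self.tag()
            if t in MODIFIER_TAGS:
                children.append(self.take())
            elif t in UNIT_TAGS and (
                self.tag(1) in MODIFIER_TAGS
                or self.tag(1) in NOUN_TAGS
                or (self.tag(1) or "").startswith("OSCAR-")
            ):
                # unit used attributively, e.g. "a 25 ml three-necked flask"
                children.append(self.take())
            else:
                break
        noun_context = bool(children)
        first = self.p_nounitem(noun_context)
        if first is None:
            self.i = start
            return None
        children.extend(first)
        while self.tag() in {"CC", "COMMA"}:
            mark = self.i
            sep = self.take()
            item = self.p_nounitem(noun_context)
            if item is None:
                self.i = mark
                break
            children.append(sep)
            children.extend(item)
        return PhraseNode("NounPhrase", children=children)

    def p_nounitem(self, noun_context: bool) -> list[PhraseNode] | None:
        t = self.tag()
        if t is not None and t.startswith("OSCAR-"):
            return [self.p_molecule()]
        if t == "CD-BOLD":
            items = [self.take()]
            qty = self.p_quantity_group()
            if qty is not None:
                items.append(qty)
            return items
        items: list[PhraseNode] = []
        if t in NOUN_TAGS:
            items.append(self.take())
        elif noun_context and t is not None and t.startswith("VB-"):
            # action verb used nominally: "the precipitate", "the extracts"
            items.append(self.take())
        else:
            return None
        while self.tag() in NOUN_TAGS:
            items.append(self.take())
        if self.tag() == "CD-BOLD":
            items.append(self.take())
        qty = self.p_quantity_group()
        if qty is not None:
            items.append(qty)
        return items

    def p_molecule(self) -> PhraseNode:
        children: list[PhraseNode] = []
        while (self.tag() or "").startswith("OSCAR-"):
            children.append(self.take())
        if self.tag() == "CD-BOLD":
            children.append(self.take())
        qty = self.p_quantity_group()
        if qty is not None:
            children.append(qty)
        return PhraseNode("MOLECULE", children=children)

    def p_quantity_group(self) -> PhraseNode | None:
        """A bracketed data phrase: ``( 0.63 g , 4.56 mmol )``."""
        if self.tag() != "LRB":
            return None
        depth = 0
        j = self.i
        end = None
        while j < len(self.toks):
            t = self.toks[j].tag
            if t == "LRB":
                depth += 1
            elif t == "RRB":
                depth -= 1
                if depth == 0:
                    end = j
                    break
            j += 1
        if end is None:
            return None
        inner = self.toks[self.i + 1 : end]
        for tt in inner:
            if tt.tag in _QTY_TAGS or tt.tag == "VB-YIELD":
                continue
            return None  # bracketed prose / molecule, not a data phrase
        children = [PhraseNode.leaf(tt) for tt in self.toks[self.i : end + 1]]
        self.i = end + 1
        return PhraseNode("QUANTITY", children=children)

    def p_parenthetical(self) -> PhraseNode | None:
        """A bracketed noun phrase, e.g. the drying agent in "dried (MgSO4)"."""
        if self.tag() != "LRB":
            return None
        start = self.i
        lrb = self.take()
        inner = self.p_nounphrase()
        if inner is None or self.tag() != "RRB":
            self.i = start
            return None
        rrb = self.take()
        return PhraseNode("NounPhrase", children=[lrb, *inner.children, rrb])

    def p_prepphrase(self) -> PhraseNode | None:
        if self.tag() not in {"IN", "TO"}:
            return None
        start = self.i
        prep = self.take()
        complement: PhraseNode | None = self.p_nounphrase()
        if complement is None:
            t = self.tag()
            if prep.label == "IN" and t is not None and (
                t.startswith("VB-") or t == "VBG"
            ):
                complement = self.take()  # gerund: "under stirring"
            else:
                complement = self.p_parenthetical()
        if complement is None:
            self.i = start
            return None
        return PhraseNode("PrepPhrase", children=[prep, complement])

    def _is_verb(self, t: str | None) -> bool:
        return t is not None and (
            t in {"VBD", "VBG", "VBN", "VB"} or t.startswith("VB-")
        )

    def p_verbphrase(self) -> PhraseNode | None:
        start = self.i
        children: list[PhraseNode] = []
        if self.tag() == "TO" and self._is_verb(self.tag(1)):
            children.append(self.take())  # infinitival "to give ..."
        while self.tag() == "RB":
            children.append(self.take())
        verbs: list[TaggedToken] = []
        while True:
            t = self.tag()
            if self._is_verb(t):
                verbs.append(self.toks[self.i])
                children.append(self.take())
            elif t == "RB" and self._is_verb(self.tag(1)):
                children.append(self.take())
            else:
                break
        if not verbs:
            self.i = start
            return None
        complements = 0
        while True:
            node = (
                self.p_prepphrase()
                or self.p_quantity_group()
                or self.p_parenthetical()
                or self.p_nounphrase()
            )
            if node is not None:
                children.append(node)
                complements += 1
                continue
            if self.tag() == "RB":
                children.append(self.take())
                continue
            break
        aux_only = all(
            not v.tag.startswith("VB-") and v.surface.lower() in _AUX for v in verbs
        )
        if aux_only and complements == 0:
            self.i = start
            return None
        return PhraseNode("VerbPhrase", children=children)


def parse_sentence(tagged: list[TaggedToken]) -> PhraseNode:
    """Parse one fully tagged sentence into its phrase tree.

    Never raises on grammatical failure: unparseable stretches become
    ``Unmatched`` nodes and the leaf-partition invariant always holds.
    """
    return _Parser(tagged).p_sentence()


def ast_leaf_tokens(node: PhraseNode) -> list[TaggedToken]:
    """In-order sequence of the tree's leaf tokens."""
    return node.leaf_tokens()


def parse_quantity(tagged: list[TaggedToken]) -> list[Quantity]:
    """Parse a bracketed data phrase into typed :class:`Quantity` values.

    ``tagged`` must begin with a left-bracket token.  Comma-separated
    entries become one quantity each; ``5 × 50 cm3`` style entries yield a
    single volume with a ``repeat`` attribute; a bare number inside the
    brackets is flagged with kind ``"unknown"``.
    """
    if not tagged or tagged[0].tag != "LRB":
        raise ValueError("quantity group must start with a left bracket")
    depth = 0
    inner: list[TaggedToken] = []
    for tt in tagged:
        if tt.tag == "LRB":
            depth += 1
            if depth == 1:
                continue
        elif tt.tag == "RRB":
            depth -= 1
            if depth == 0:
                break
        inner.append(tt)

    groups: list[list[TaggedToken]] = [[]]
    for tt in inner:
        if tt.tag == "COMMA":
            groups.append([])
        else:
            groups[-1].append(tt)

    out: list[Quantity] = []
    for group in groups:
        if not group:
            continue
        qualifier = None
        repeat = None
        value = None
        unit = ""
        kind = None
        k = 0
        while k < len(group):
            tt = group[k]
            if tt.tag == "RB":
                qualifier = tt.surface
            elif tt.tag == "CD":
                if (
                    k + 2 < len(group)
                    and group[k + 1].tag == "TIMES"
                    and group[k + 2].tag == "CD"
                ):
                    repeat = int(float(tt.surface))
                    value = float(group[k + 2].surface)
                    k += 2
                else:
                    value = float(tt.surface)
            elif tt.tag in _UNIT_KIND:
                unit = tt.surface
                kind = _UNIT_KIND[tt.tag]
            k += 1
        if value is None:
            continue
        if kind is None:
            kind = "unknown"
        out.append(Quantity(kind=kind, value=value, unit=unit,
                            qualifier=qualifier, repeat=repeat))
    return out
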