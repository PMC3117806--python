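"""XML serialisation of phrase trees.

Element names mirror node labels exactly (``ActionPhrase`` with its
``type`` attribute, ``NounPhrase``, ``MOLECULE``, hyphenated leaf tags
such as ``OSCAR-CM`` and ``VB-ADD``); leaf text is the token surface.
Serialisation refuses trees that violate the leaf-partition invariant,
and deserialisation rejects unknown element names, so a round trip is
the identity on structure and surfaces (character offsets are not
serialised).
"""

from __future__ import annotations

from lxml import etree

from .phrase_parser import PHRASE_LABELS, PhraseNode
from .preprocess import Token
from .taggers import (
    ACTION_FAMILIES,
    TagNamespace,
    TaggedToken,
    UNIT_TAGS,
    family_to_verb_tag,
)

__all__ = [
    "ast_to_xml",
    "xml_to_ast",
    "to_xml_string",
    "build_schema",
    "validate",
    "XMLDialectError",
]


class XMLDialectError(ValueError):
    """Raised for XML that is not in the phrase-tree dialect."""


_REGEX_LEAF_TAGS = (
    frozenset(family_to_verb_tag(f) for f in ACTION_FAMILIES)
    | UNIT_TAGS
    | frozenset({"NN-STATE", "NN-MIXTURE", "NN-SOLUTION", "CD-BOLD"})
)
_POS_LEAF_TAGS = frozenset(
    """NN NNS NNP JJ RB VB VBD VBG VBN CD DT CC TO IN PRP WDT SYM
    STOP COMMA LRB RRB LSQB RSQB COLON SEMICOLON TIMES SLASH DASH""".split()
)
_CHEM_LEAF_TAGS = frozenset(
    "OSCAR-CM OSCAR-RN OSCAR-ONT OSCAR-CPR OSCAR-ASE OSCAR-CJ".split()
)
KNOWN_LEAF_TAGS = _REGEX_LEAF_TAGS | _POS_LEAF_TAGS | _CHEM_LEAF_TAGS

#: Internal element names; ``Document`` wraps multi-sentence output.
INTERNAL_LABELS = PHRASE_LABELS | {"Document"}


def _check_partition(root: PhraseNode) -> None:
    tokens = root.leaf_tokens()
    last = None
    for tt in tokens:
        if tt is None:
            raise ValueError("leaf node without a token")
        if last is not None and tt.token.id <= last:
            raise ValueError(
                f"leaf tokens out of order at token id {tt.token.id}: "
                "tree violates the leaf-partition invariant"
            )
        last = tt.token.id


def ast_to_xml(root: PhraseNode) -> etree._Element:
    """Serialise a phrase tree to an XML element.

    Child order equals element order; the ``type`` attribute is written
    first.  Trees whose leaves are out of order (a broken partition) are
    refused with a diagnostic.
    """
    _check_partition(root)
    return _to_element(root)


def _to_element(node: PhraseNode) -> etree._Element:
    el = etree.Element(node.label)
    if "type" in node.attributes:
        el.set("type", node.attributes["type"])
    for key in sorted(k for k in node.attributes if k != "type"):
        el.set(key, node.attributes[key])
    if node.is_leaf:
        el.text = node.token.surface
    for child in node.children:
        el.append(_to_element(child))
    return el


def to_xml_string(root: PhraseNode, pretty: bool = True) -> str:
    return etree.tostring(
        ast_to_xml(root), pretty_print=pretty, encoding="unicode"
    )


def xml_to_ast(doc: str | bytes | etree._Element) -> PhraseNode:
    """Parse dialect XML back into a phrase tree.

    Inverse of :func:`ast_to_xml` up to whitespace and offsets: leaf
    tokens are rebuilt with synthetic consecutive offsets.  Unknown
    element names raise :class:`XMLDialectError` naming the element.
    """
    if isinstance(doc, (str, bytes)):
        if isinstance(doc, str):
            doc = doc.encode("utf-8")
        doc = etree.fromstring(doc)
    counter = {"pos": 0, "id": 0}
    return _from_element(doc, counter)


def _leaf_namespace(tag: str) -> TagNamespace:
    if tag in _CHEM_LEAF_TAGS:
        return TagNamespace.CHEM
    if tag in _REGEX_LEAF_TAGS:
        return TagNamespace.REGEX
    return TagNamespace.POS


def _from_element(el: etree._Element, counter: dict) -> PhraseNode:
    tag = el.tag
    children = list(el)
    attributes = dict(el.attrib)
    if children:
        if tag not in INTERNAL_LABELS:
            raise XMLDialectError(f"unknown element {tag!r}")
        return PhraseNode(
            tag,
            children=[_from_element(c, counter) for c in children],
            attributes=attributes,
        )
    if tag in INTERNAL_LABELS:  # e.g. an empty Sentence
        return PhraseNode(tag, attributes=attributes)
    if tag not in KNOWN_LEAF_TAGS:
        raise XMLDialectError(f"unknown element {tag!r}")
    surface = (el.text or "").strip()
    if not surface:
        raise XMLDialectError(f"leaf element {tag!r} has no text")
    start = counter["pos"]
    token = Token(surface, start, start + len(surface), counter["id"])
    counter["pos"] = start + len(surface) + 1
    counter["id"] += 1
    return PhraseNode(tag, token=TaggedToken(token, tag, _leaf_namespace(tag)))


# ---------------------------------------------------------------------------
# schema

_RNG_NS = "http://relaxng.org/ns/structure/1.0"


def _rng() -> etree._Element:
    def E(tag: str, **attrs: str) -> etree._Element:
        return etree.Element(f"{{{_RNG_NS}}}{tag}", **attrs)

    grammar = E("grammar")
    start = E("start")
    ref = E("ref", name="node")
    start.append(ref)
    grammar.append(start)

    node_def = E("define", name="node")
    node_choice = E("choice")
    node_def.append(node_choice)

    for label in sorted(INTERNAL_LABELS):
        el = E("element", name=label)
        if label == "ActionPhrase":
            attr = E("attribute", name="type")
            choice = E("choice")
            for family in ACTION_FAMILIES:
                value = E("value")
                value.text = family
                choice.append(value)
            attr.append(choice)
            el.append(attr)
        zom = E("zeroOrMore")
        inner = E("ref", name="node")
        zom.append(inner)
        el.append(zom)
        node_choice.append(el)

    for tag in sorted(KNOWN_LEAF_TAGS):
        el = E("element", name=tag)
        el.append(E("text"))
        node_choice.append(el)

    grammar.append(node_def)
    return grammar


_SCHEMA: etree.RelaxNG | None = None


def build_schema() -> etree.RelaxNG:
    """RELAX NG schema for the phrase-tree XML dialect."""
    global _SCHEMA
    if _SCHEMA is None:
        _SCHEMA = etree.RelaxNG(_rng())
    return _SCHEMA


def validate(doc: etree._Element | PhraseNode) -> bool:
    """True iff the document (or tree) is valid dialect XML."""
    if isinstance(doc, PhraseNode):
        doc = ast_to_xml(doc)
    return build_schema().validate(doc)
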