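"""End-to-end document processing: raw text to parsed, labelled document.

Ties the stages together: normalise → tokenise → sentence-split →
cascade-tag → phrase-parse → action identification → role inference.
A title line (a leading segment ending in a colon, as preparations are
headed) is recognised and used for product identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from . import xml_io
from .action_roles import (
    ActionPhrase,
    PreparationSummary,
    RoleAssignment,
    assign_roles,
    identify_actions,
    summarize_preparation,
)
from .evaluation import AnnotationSpan, AnnotatorSet
from .phrase_parser import PhraseNode, Quantity, parse_quantity, parse_sentence
from .preprocess import Token, normalize_text, split_sentences, tokenize
from .taggers import ChemicalLexicon, TaggedToken, TagRules, cascade_tag, ingest_ner_xml

__all__ = ["ParsedDocument", "parse_document", "annotate_corpus"]


@dataclass
class ParsedDocument:
    """A fully processed document with all intermediate artefacts."""

    raw: str
    source_id: str
    tokens: list[Token]
    segments: list[list[TaggedToken]]
    title: PhraseNode | None
    sentences: list[PhraseNode]
    actions: list[ActionPhrase]
    roles: list[RoleAssignment] = field(default_factory=list)

    @property
    def summary(self) -> PreparationSummary:
        return summarize_preparation(
            self.sentences,
            self.actions,
            self.roles,
            title=self.title,
            source_id=self.source_id,
        )

    def annotation_spans(self) -> list[AnnotationSpan]:
        """The machine's phrase annotations (top-level actions) as spans."""
        spans = []
        for action in self.actions:
            start, end = action.span
            spans.append(
                AnnotationSpan(
                    start, end, self.raw[start:end], action.type.name,
                    doc_id=self.source_id,
                )
            )
        return spans

    def quantity_groups(self) -> list[tuple[str, list[Quantity]]]:
        """All bracketed data phrases with the phrase they are attached to."""
        out: list[tuple[str, list[Quantity]]] = []

        def visit(node: PhraseNode) -> None:
            if node.is_leaf:
                return
            for i, child in enumerate(node.children):
                if child.label == "QUANTITY":
                    owner = " ".join(
                        tt.surface
                        for sib in node.children[:i]
                        for tt in sib.leaf_tokens()
                    )
                    out.append((owner, parse_quantity(child.leaf_tokens())))
                else:
                    visit(child)

        for tree in ([self.title] if self.title else []) + self.sentences:
            visit(tree)
        return out

    def to_xml(self) -> etree._Element:
        """The document as dialect XML (title first when present)."""
        root = PhraseNode("Document")
        if self.title is not None:
            root.children.append(self.title)
        root.children.extend(self.sentences)
        return xml_io.ast_to_xml(root)


def parse_document(
    text: str,
    *,
    source_id: str = "",
    lexicon: ChemicalLexicon | None = None,
    rules: TagRules | None = None,
    bold_dialect: str = "positional",
    ner_xml: str | bytes | None = None,
) -> ParsedDocument:
    """Run the full pipeline over one plain-text document.

    ``ner_xml`` may carry pre-computed chemical NER annotations in the
    ``ne``-element dialect; they then replace the bundled lexicon
    tagger's output.
    """
    normalized = normalize_text(text)
    tokens = tokenize(normalized)
    entities = ingest_ner_xml(ner_xml, tokens) if ner_xml is not None else None
    tagged = cascade_tag(
        tokens, lexicon, rules, entities=entities, bold_dialect=bold_dialect
    )
    by_id = {tt.token.id: tt for tt in tagged}
    segments = [
        [by_id[tok.id] for tok in seg] for seg in split_sentences(tokens)
    ]

    title: PhraseNode | None = None
    body_segments = segments
    if (
        len(segments) > 1
        and segments[0]
        and segments[0][-1].surface == ":"
    ):
        title = parse_sentence(segments[0])
        body_segments = segments[1:]

    sentences = [parse_sentence(seg) for seg in body_segments]
    actions: list[ActionPhrase] = []
    if title is not None:
        actions.extend(identify_actions(title))
    for tree in sentences:
        actions.extend(identify_actions(tree))
    roles = assign_roles(sentences, actions, title=title)
    return ParsedDocument(
        raw=text,
        source_id=source_id,
        tokens=tokens,
        segments=segments,
        title=title,
        sentences=sentences,
        actions=actions,
        roles=roles,
    )


def annotate_corpus(
    texts: list[str],
    ids: list[str] | None = None,
    annotator_id: str = "machine",
    **kwargs,
) -> AnnotatorSet:
    """Run the pipeline over a corpus and collect its spans as an annotator."""
    ids = ids or [f"doc{i + 1}" for i in range(len(texts))]
    spans: list[AnnotationSpan] = []
    for text, doc_id in zip(texts, ids):
        doc = parse_document(text, source_id=doc_id, **kwargs)
        spans.extend(doc.annotation_spans())
    return AnnotatorSet(annotator_id, spans)
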