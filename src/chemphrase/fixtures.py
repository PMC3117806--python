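"""Synthetic experimental paragraphs, gold annotations and noisy annotators.

Paragraphs are produced by instantiating one grammar-conformant sentence
template per action family (chemicals, solvents, quantities and
conditions sampled from small fixed pools), so every pipeline stage can
be exercised — and its recovery of the generating labels measured —
without any external corpus.  Simulated annotators are derived from the
gold annotations by boundary jitter, label confusion and span dropping
at configurable rates, emulating the boundary ambiguity real annotators
exhibit (e.g. whether a leading "To a ..." belongs to the phrase).

All sampling flows through one seeded random generator; identical seeds
give identical output.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .evaluation import AnnotationSpan, AnnotatorSet
from .phrase_parser import PhraseNode
from .preprocess import Token
from .taggers import ACTION_FAMILIES, TagNamespace, TaggedToken, family_to_verb_tag
from .taggers import _data_lines

__all__ = [
    "GenerationConfig",
    "ParagraphFixture",
    "generate_paragraph",
    "perturb_annotations",
    "simulate_annotators",
    "sample_derivation",
]

CHEMICALS = [
    "thiophenol", "benzoyl peroxide", "sodium chloride", "styrene",
    "aniline", "pyridine", "methyl methacrylate", "phenol",
]
SOLVENTS = [
    "water", "methanol", "ethanol", "toluene", "THF", "DMF",
    "dichloromethane", "diethyl ether", "ethyl acetate",
]
GASES = ["argon", "nitrogen"]
COLOURS = ["white", "yellow", "colourless", "brown", "red"]
STATES = ["oil", "solid", "foam", "gum", "powder"]


def _load_templates() -> dict[str, str]:
    templates = dict(ln.split("\t") for ln in _data_lines("templates.tsv"))
    missing = set(ACTION_FAMILIES) - set(templates)
    if missing:
        raise RuntimeError(f"templates missing for {sorted(missing)}")
    return templates


_TEMPLATES: dict[str, str] | None = None


def _templates() -> dict[str, str]:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = _load_templates()
    return _TEMPLATES


@dataclass
class GenerationConfig:
    """Knobs for synthetic paragraph and annotator generation.

    ``action_mix`` is a distribution over the 21 action families
    (uniform when omitted); perturbation rates control the simulated
    annotators.  Boundary jitter is measured in whole words.
    """

    seed: int = 0
    n_sentences: int = 10
    action_mix: dict[str, float] | None = None
    boundary_jitter_tokens: int = 0
    label_confusion_prob: float = 0.0
    drop_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("label_confusion_prob", "drop_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.boundary_jitter_tokens < 0:
            raise ValueError("boundary_jitter_tokens must be >= 0")
        if self.action_mix is not None:
            unknown = set(self.action_mix) - set(ACTION_FAMILIES)
            if unknown:
                raise ValueError(f"unknown action families {sorted(unknown)}")
            total = sum(self.action_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"action_mix sums to {total}, not 1")
            if any(p < 0 for p in self.action_mix.values()):
                raise ValueError("action_mix probabilities must be >= 0")


@dataclass
class ParagraphFixture:
    """A generated paragraph with its gold annotations."""

    text: str
    sentences: list[str]
    labels: list[str]
    spans: list[AnnotationSpan] = field(default_factory=list)


def _fill(template: str, rng: random.Random) -> str:
    values = {
        "CM": rng.choice(CHEMICALS),
        "SOLV": rng.choice(SOLVENTS),
        "GAS": rng.choice(GASES),
        "COLOUR": rng.choice(COLOURS),
        "STATE": rng.choice(STATES),
        "BOLD": str(rng.randint(1, 99)),
        "N": str(rng.randint(5, 500)),
        "N2": str(rng.randint(5, 500)),
        "K": str(rng.randint(2, 5)),
        "H": str(rng.randint(1, 48)),
        "D": str(rng.randint(1, 7)),
        "PCT": str(rng.randint(40, 99)),
    }
    sentence = template.format(**values)
    return sentence[0].upper() + sentence[1:]  # sentence-initial capital


def generate_paragraph(
    config: GenerationConfig, rng: random.Random | None = None
) -> ParagraphFixture:
    """Instantiate ``n_sentences`` templates into a gold-annotated paragraph.

    Each sentence realises one action family drawn from ``action_mix``;
    its gold span covers the sentence text without the terminal stop.
    Deterministic under a fixed seed.
    """
    rng = rng or random.Random(config.seed)
    if config.action_mix is None:
        families = [
            ACTION_FAMILIES[rng.randrange(len(ACTION_FAMILIES))]
            for _ in range(config.n_sentences)
        ]
    else:
        names = sorted(config.action_mix)
        weights = [config.action_mix[n] for n in names]
        families = rng.choices(names, weights=weights, k=config.n_sentences)

    sentences = [_fill(_templates()[family], rng) for family in families]
    text = " ".join(sentences)
    spans: list[AnnotationSpan] = []
    pos = 0
    for sentence, family in zip(sentences, families):
        start = text.index(sentence, pos)
        end = start + len(sentence)
        pos = end
        core_end = end - 1 if sentence.endswith(".") else end
        spans.append(
            AnnotationSpan(start, core_end, text[start:core_end], family)
        )
    return ParagraphFixture(text, sentences, list(families), spans)


def perturb_annotations(
    gold: list[AnnotationSpan],
    config: GenerationConfig,
    text: str,
    rng: random.Random | None = None,
) -> list[AnnotationSpan]:
    """Derive a noisy annotator from gold spans.

    Each span independently: dropped with ``drop_prob``; both boundaries
    moved by up to ``boundary_jitter_tokens`` whole words; label replaced
    with a different family at ``label_confusion_prob``.  Output is
    re-sorted by position.  All rates zero reproduces the gold spans.
    """
    rng = rng or random.Random(config.seed)
    words = [m.span() for m in re.finditer(r"\S+", text)]
    starts = [s for s, _ in words]
    ends = [e for _, e in words]

    out: list[AnnotationSpan] = []
    for span in gold:
        if rng.random() < config.drop_prob:
            continue
        start, end = span.start, span.end
        j = config.boundary_jitter_tokens
        if j > 0:
            si = min(
                range(len(starts)), key=lambda i: abs(starts[i] - start)
            )
            ei = min(range(len(ends)), key=lambda i: abs(ends[i] - end))
            si = max(0, min(len(starts) - 1, si + rng.randint(-j, j)))
            ei = max(0, min(len(ends) - 1, ei + rng.randint(-j, j)))
            if starts[si] < ends[ei]:
                start, end = starts[si], ends[ei]
        label = span.label
        if rng.random() < config.label_confusion_prob:
            others = [f for f in ACTION_FAMILIES if f != label]
            label = others[rng.randrange(len(others))]
        out.append(
            AnnotationSpan(start, end, text[start:end], label, span.doc_id)
        )
    return sorted(out, key=lambda s: (s.doc_id, s.start, s.end))


def simulate_annotators(
    config: GenerationConfig, n_annotators: int = 4
) -> tuple[ParagraphFixture, AnnotatorSet, list[AnnotatorSet]]:
    """Generate a paragraph, its gold annotator and ``n`` noisy annotators."""
    rng = random.Random(config.seed)
    fixture = generate_paragraph(config, rng)
    gold = AnnotatorSet("gold", list(fixture.spans))
    annotators = [
        AnnotatorSet(
            f"annotator{i + 1}",
            perturb_annotations(fixture.spans, config, fixture.text, rng),
        )
        for i in range(n_annotators)
    ]
    return fixture, gold, annotators


# ---------------------------------------------------------------------------
# grammar-based sampling with a known derivation tree

def _leaf(surface: str, tag: str, state: dict) -> PhraseNode:
    ns = (
        TagNamespace.CHEM
        if tag.startswith("OSCAR-")
        else TagNamespace.REGEX
        if tag.startswith("VB-") or tag.startswith("NN-") or tag == "CD-BOLD"
        else TagNamespace.POS
    )
    token = Token(surface, state["pos"], state["pos"] + len(surface), state["id"])
    state["pos"] += len(surface) + 1
    state["id"] += 1
    return PhraseNode.leaf(TaggedToken(token, tag, ns))


def _gen_quantity(rng: random.Random, state: dict) -> PhraseNode:
    children = [_leaf("(", "LRB", state)]
    entries = rng.randint(1, 2)
    units = [("g", "NN-MASS"), ("mmol", "NN-MOLAR"), ("ml", "NN-VOL")]
    for k in range(entries):
        if k:
            children.append(_leaf(",", "COMMA", state))
        value = f"{rng.randint(1, 99) / 10:.1f}"
        unit, tag = units[rng.randrange(len(units))]
        children.append(_leaf(value, "CD", state))
        children.append(_leaf(unit, tag, state))
    children.append(_leaf(")", "RRB", state))
    return PhraseNode("QUANTITY", children=children)


def _gen_molecule(rng: random.Random, state: dict) -> PhraseNode:
    name = rng.choice(CHEMICALS)
    children = [_leaf(part, "OSCAR-CM", state) for part in name.split()]
    if rng.random() < 0.5:
        children.append(_gen_quantity(rng, state))
    return PhraseNode("MOLECULE", children=children)


def _gen_nounphrase(rng: random.Random, state: dict) -> PhraseNode:
    children: list[PhraseNode] = []
    if rng.random() < 0.5:
        children.append(_leaf("the", "DT", state))
    children.append(_gen_molecule(rng, state))
    if rng.random() < 0.3:
        children.append(_leaf("and", "CC", state))
        children.append(_gen_molecule(rng, state))
    return PhraseNode("NounPhrase", children=children)


def sample_derivation(
    rng: random.Random,
) -> tuple[list[TaggedToken], PhraseNode]:
    """Sample a tagged sentence from the grammar's own production rules.

    Returns the token sequence together with the derivation tree that
    produced it, for checking that the parser recovers the generating
    structure (sentence → nounphrase verbphrase; molecule → chemical
    tokens with an optional bracketed quantity; verbphrase → auxiliary,
    action verb, optional prepositional phrase).
    """
    state = {"pos": 0, "id": 0}
    np = _gen_nounphrase(rng, state)
    family = ACTION_FAMILIES[rng.randrange(len(ACTION_FAMILIES))]
    stem = {"ApparatusAction": "seal"}.get(family, family.lower())
    verb = stem + ("d" if stem.endswith("e") else "ed")
    vp_children = [
        _leaf("was", "VBD", state),
        _leaf(verb, family_to_verb_tag(family), state),
    ]
    if rng.random() < 0.7:
        prep, tag = rng.choice([("to", "TO"), ("in", "IN"), ("with", "IN")])
        vp_children.append(
            PhraseNode(
                "PrepPhrase",
                children=[_leaf(prep, tag, state), _gen_nounphrase(rng, state)],
            )
        )
    vp = PhraseNode("VerbPhrase", children=vp_children)
    stop = _leaf(".", "STOP", state)
    tree = PhraseNode("Sentence", children=[np, vp, stop])
    return tree.leaf_tokens(), tree
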