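"""Three-stage cascading tagger: chemical NER, domain regexes, English POS.

Every token receives exactly one tag.  Chemical entities are recognised
first (lexicon phrases plus systematic-name morphology, or ingested from
an external NER's ``ne``-element XML); a domain regex tagger then marks
chemistry-specific vocabulary (action verbs, units, physical states, bold
compound references); whatever is left falls through to a bundled
deterministic Penn-tag part-of-speech tagger.  A token claimed at one
stage is invisible to later stages.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

from .preprocess import Token, normalize_text, tokenize

__all__ = [
    "TagNamespace",
    "NamedEntity",
    "TaggedToken",
    "ChemicalLexicon",
    "TagRules",
    "ACTION_FAMILIES",
    "family_to_verb_tag",
    "verb_tag_to_family",
    "tag_chemicals",
    "ingest_ner_xml",
    "tag_regex",
    "tag_pos",
    "cascade_tag",
]

log = logging.getLogger(__name__)

NE_TYPES = frozenset({"CM", "RN", "ONT", "CPR", "ASE", "CJ"})

#: The closed set of 21 action families.
ACTION_FAMILIES = (
    "Add", "ApparatusAction", "Concentrate", "Cool", "Degass", "Dissolve",
    "Dry", "Extract", "Filter", "Heat", "Partition", "Precipitate",
    "Purify", "Quench", "Recover", "Remove", "Stir", "Synthesize", "Wait",
    "Wash", "Yield",
)

_FAMILY_TAG_OVERRIDES = {"ApparatusAction": "VB-APPARATUS"}


def family_to_verb_tag(family: str) -> str:
    """Regex-namespace tag for an action family, e.g. ``Add -> VB-ADD``."""
    return _FAMILY_TAG_OVERRIDES.get(family, "VB-" + family.upper())


_TAG_TO_FAMILY = {family_to_verb_tag(f): f for f in ACTION_FAMILIES}


def verb_tag_to_family(tag: str) -> str | None:
    return _TAG_TO_FAMILY.get(tag)


class TagNamespace(str, Enum):
    CHEM = "CHEM"
    REGEX = "REGEX"
    POS = "POS"


@dataclass(frozen=True)
class NamedEntity:
    """A chemical named entity, possibly spanning several tokens."""

    id: str
    surface: str
    type: str
    confidence: float | None = None
    token_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in NE_TYPES:
            raise ValueError(f"unknown entity type {self.type!r}")


@dataclass(frozen=True)
class TaggedToken:
    token: Token
    tag: str
    namespace: TagNamespace

    @property
    def surface(self) -> str:
        return self.token.surface


def _data_lines(name: str) -> list[str]:
    text = resources.files("chemphrase.data").joinpath(name).read_text("utf-8")
    return [ln for ln in text.splitlines() if ln and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# chemical NER

#: Spelled-out element names (lower case) recognised as CM tokens.
ELEMENT_NAMES = frozenset(
    """hydrogen helium lithium beryllium boron carbon oxygen fluorine neon
    sodium magnesium aluminium aluminum silicon phosphorus sulfur sulphur
    chlorine potassium calcium titanium chromium manganese iron cobalt
    nickel copper zinc bromine silver tin iodine platinum gold mercury
    lead""".split()
)

#: Systematic-name suffixes that mark a token as a chemical name.
CHEM_SUFFIXES = (
    "ol", "ene", "ane", "yne", "ide", "ine", "one", "ate", "ite", "ium",
    "ose", "yl", "amide", "amine",
)

#: Ordinary English words that would otherwise match a chemical suffix.
ENGLISH_BLOCKLIST = frozenset(
    """state plate late gate rate date separate indicate accurate machine
    line mine fine nine wine routine combine determine examine one done
    gone alone none phone stone zone cool tool pool school control
    protocol scene gene plane crane membrane side wide guide provide
    slide inside outside aside decide medium premium those whose close
    purpose dispose suppose came become outcome welcome sample same time
    came table stable double triple little bottle while whole
    mol mmol nmol µmol umol pmol kmol gasoline""".split()
)

#: Upper-case acronyms that look like formulae but are not compounds.
ACRONYM_BLOCKLIST = frozenset(
    "NMR UV IR TLC HPLC GC MS MP BP RT II III IV VI".split()
)

_FORMULA_RE = re.compile(r"^(?:[A-Z][a-z]?[0-9]*){2,}$")


def _name_candidate(surface: str) -> bool:
    """Locant morphology: digits + hyphens + a substantive letter run."""
    if "-" not in surface or not re.search(r"[0-9]", surface):
        return False
    return len(re.sub(r"[^A-Za-z]", "", surface)) >= 4


@dataclass
class ChemicalLexicon:
    """Phrase lexicon plus morphology rules for chemical-entity tagging.

    ``phrases`` maps a tuple of lower-cased token surfaces (the phrase as
    it tokenises) to an entity type.  Morphology covers element names,
    molecular-formula strings, systematic suffixes and locant patterns.
    """

    phrases: dict[tuple[str, ...], str] = field(default_factory=dict)
    suffixes: tuple[str, ...] = CHEM_SUFFIXES
    blocklist: frozenset[str] = ENGLISH_BLOCKLIST

    def __post_init__(self) -> None:
        self._max_len = max((len(k) for k in self.phrases), default=1)

    @classmethod
    def default(cls) -> "ChemicalLexicon":
        phrases: dict[tuple[str, ...], str] = {}
        for line in _data_lines("chem_lexicon.tsv"):
            phrase, netype = line.split("\t")
            key = tuple(
                t.surface.lower() for t in tokenize(normalize_text(phrase))
            )
            phrases[key] = netype
        return cls(phrases=phrases)

    def add(self, phrase: str, netype: str = "CM") -> None:
        key = tuple(t.surface.lower() for t in tokenize(normalize_text(phrase)))
        self.phrases[key] = netype
        self._max_len = max(self._max_len, len(key))

    def match_phrase(self, surfaces: list[str], i: int) -> tuple[int, str] | None:
        """Longest phrase match starting at position ``i``; leftmost ties win."""
        for length in range(min(self._max_len, len(surfaces) - i), 0, -1):
            key = tuple(s.lower() for s in surfaces[i : i + length])
            if key in self.phrases:
                return length, self.phrases[key]
        return None

    def match_morphology(self, surface: str) -> str | None:
        low = surface.lower()
        if low in self.blocklist:
            return None
        if low in ELEMENT_NAMES:
            return "CM"
        if _name_candidate(surface):
            return "CM"
        if (
            len(surface) >= 2
            and surface not in ACRONYM_BLOCKLIST
            and _FORMULA_RE.match(surface)
        ):
            return "CM"
        if surface.isalpha() and len(surface) >= 4:
            if low.startswith("poly") and len(low) >= 8:
                return "CM"
            for suf in self.suffixes:
                if low.endswith(suf) and len(low) > len(suf) + 1:
                    return "CM"
        return None


_DEFAULT_LEXICON: ChemicalLexicon | None = None


def default_lexicon() -> ChemicalLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = ChemicalLexicon.default()
    return _DEFAULT_LEXICON


def tag_chemicals(
    tokens: list[Token], lexicon: ChemicalLexicon | None = None
) -> list[NamedEntity]:
    """Recognise chemical entities over ``tokens``.

    Multi-token lexicon phrases win over single-token morphology, longest
    match first, ties broken leftmost.  Lexicon and morphology hits are
    emitted with confidence 1.0.  Tokens that match nothing are simply
    left for the later cascade stages.
    """
    lexicon = lexicon or default_lexicon()
    surfaces = [t.surface for t in tokens]
    entities: list[NamedEntity] = []
    i = 0
    n = 0
    while i < len(tokens):
        hit = lexicon.match_phrase(surfaces, i)
        if hit is not None:
            length, netype = hit
            n += 1
            entities.append(
                NamedEntity(
                    id=f"n{n}",
                    surface=" ".join(surfaces[i : i + length]),
                    type=netype,
                    confidence=1.0,
                    token_ids=tuple(t.id for t in tokens[i : i + length]),
                )
            )
            i += length
            continue
        netype = lexicon.match_morphology(surfaces[i])
        if netype is not None:
            n += 1
            entities.append(
                NamedEntity(
                    id=f"n{n}",
                    surface=surfaces[i],
                    type=netype,
                    confidence=1.0,
                    token_ids=(tokens[i].id,),
                )
            )
        i += 1
    return entities


def ingest_ner_xml(
    xml: str | bytes, tokens: list[Token] | None = None
) -> list[NamedEntity]:
    """Read pre-computed NER annotations in the ``ne``-element XML dialect.

    Each ``ne`` element carries ``id``, ``surface``, ``type`` and an
    optional ``confidence`` attribute.  When ``tokens`` are supplied, each
    entity is aligned to the leftmost unused run of tokens whose surfaces
    reproduce the entity surface; entities that cannot be aligned are
    logged and skipped.  Malformed XML raises ``lxml.etree.XMLSyntaxError``.
    """
    from lxml import etree

    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    root = etree.fromstring(xml)
    elements = list(root.iter("ne"))
    if root.tag == "ne":
        elements = [root] + [e for e in elements if e is not root]

    used: set[int] = set()
    entities: list[NamedEntity] = []
    for el in elements:
        surface = (el.get("surface") or el.text or "").strip()
        netype = (el.get("type") or "CM").strip()
        conf_attr = el.get("confidence")
        confidence = float(conf_attr.strip()) if conf_attr not in (None, "") else None
        token_ids: tuple[int, ...] = ()
        if tokens is not None:
            want = [
                t.surface.lower() for t in tokenize(normalize_text(surface))
            ]
            pos = _align(tokens, want, used)
            if pos is None:
                log.warning("could not align ne surface %r to tokens; skipped", surface)
                continue
            token_ids = tuple(tokens[j].id for j in pos)
            used.update(pos)
        entities.append(
            NamedEntity(
                id=(el.get("id") or f"n{len(entities) + 1}").strip(),
                surface=surface,
                type=netype,
                confidence=confidence,
                token_ids=token_ids,
            )
        )
    return entities


def _align(
    tokens: list[Token], want: list[str], used: set[int]
) -> list[int] | None:
    if not want:
        return None
    for i in range(len(tokens) - len(want) + 1):
        span = range(i, i + len(want))
        if any(j in used for j in span):
            continue
        if [tokens[j].surface.lower() for j in span] == want:
            return list(span)
    return None


# ---------------------------------------------------------------------------
# regex tagger

UNIT_TAGS = frozenset(
    {"NN-MASS", "NN-MOLAR", "NN-VOL", "NN-PERCENT", "NN-TEMP", "NN-TIME", "NN-EQUIV"}
)


@dataclass
class TagRules:
    """Ordered regex rules plus the action-verb lexicon (first match wins)."""

    regex_rules: list[tuple[re.Pattern, str]] = field(default_factory=list)
    action_verbs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "TagRules":
        rules = [
            (re.compile(pat), tag)
            for pat, tag in (ln.split("\t") for ln in _data_lines("tag_rules.tsv"))
        ]
        verbs = dict(ln.split("\t") for ln in _data_lines("action_verbs.tsv"))
        return cls(regex_rules=rules, action_verbs=verbs)

    def match_action_verb(self, surface: str) -> str | None:
        """Action family for a surface form, with light stemming."""
        t = surface.lower()
        candidates = [t]
        if t.endswith("ies"):
            candidates.append(t[:-3] + "y")
        if t.endswith("ied"):
            candidates.append(t[:-3] + "y")
        if t.endswith("ed"):
            stem = t[:-2]
            candidates += [stem, t[:-1]]
            if len(stem) > 2 and stem[-1] == stem[-2]:
                candidates.append(stem[:-1])
        if t.endswith("ing"):
            stem = t[:-3]
            candidates += [stem, stem + "e"]
            if len(stem) > 2 and stem[-1] == stem[-2]:
                candidates.append(stem[:-1])
        if t.endswith("s") and not t.endswith("ss"):
            candidates.append(t[:-1])
        for cand in candidates:
            family = self.action_verbs.get(cand)
            if family is not None:
                return family
        return None

    def tag_for(self, surface: str) -> str | None:
        family = self.match_action_verb(surface)
        if family is not None:
            return family_to_verb_tag(family)
        for pattern, tag in self.regex_rules:
            if pattern.match(surface):
                return tag
        return None


_DEFAULT_RULES: TagRules | None = None


def default_rules() -> TagRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = TagRules.default()
    return _DEFAULT_RULES


def tag_regex(
    tokens: list[Token], rules: TagRules | None = None
) -> list[TaggedToken]:
    """Tag chemistry-domain vocabulary; non-matching tokens pass through."""
    rules = rules or default_rules()
    out = []
    for tok in tokens:
        tag = rules.tag_for(tok.surface)
        if tag is not None:
            out.append(TaggedToken(tok, tag, TagNamespace.REGEX))
    return out


# ---------------------------------------------------------------------------
# POS tagger

_PUNCT_TAGS = {
    ".": "STOP", ",": "COMMA", "(": "LRB", ")": "RRB", "[": "LSQB",
    "]": "RSQB", ":": "COLON", ";": "SEMICOLON", "×": "TIMES", "/": "SLASH",
    "-": "DASH",
}

_NUMBER_RE = re.compile(r"^[0-9]+(\.[0-9]+)?$")


def _load_pos_lexicon() -> dict[str, str]:
    return dict(ln.split("\t") for ln in _data_lines("pos_lexicon.tsv"))


_POS_LEXICON: dict[str, str] | None = None


def _pos_lexicon() -> dict[str, str]:
    global _POS_LEXICON
    if _POS_LEXICON is None:
        _POS_LEXICON = _load_pos_lexicon()
    return _POS_LEXICON


def pos_tag_word(surface: str) -> str:
    """Deterministic Penn tag for one token (lexicon, then suffix rules)."""
    if surface in _PUNCT_TAGS:
        return _PUNCT_TAGS[surface]
    lex = _pos_lexicon()
    tag = lex.get(surface) or lex.get(surface.lower())
    if tag is not None:
        return tag
    if _NUMBER_RE.match(surface):
        return "CD"
    if len(surface) == 1 and not surface.isalnum():
        return "SYM"
    if "-" in surface and re.search(r"[A-Za-z]", surface):
        return "JJ"
    low = surface.lower()
    if low.endswith(("ed", "ied")):
        return "VBD"
    if low.endswith("ing"):
        return "VBG"
    if low.endswith("ly"):
        return "RB"
    if len(low) > 3 and low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def tag_pos(tokens: list[Token]) -> list[TaggedToken]:
    """Assign a Penn tag to every token (total; the final fallback stage)."""
    return [TaggedToken(t, pos_tag_word(t.surface), TagNamespace.POS) for t in tokens]


# ---------------------------------------------------------------------------
# cascade

BOLD_DIALECTS = ("positional", "markdown", "html")

_INT_RE = re.compile(r"^[0-9]+$")
_REFERENCE_HOSTS = frozenset({"compound", "product", "compounds", "products"})


def cascade_tag(
    tokens: list[Token],
    lexicon: ChemicalLexicon | None = None,
    rules: TagRules | None = None,
    *,
    entities: list[NamedEntity] | None = None,
    bold_dialect: str = "positional",
) -> list[TaggedToken]:
    """Run the full tagging cascade; every token receives exactly one tag.

    Precedence is chemical NER > domain regex > POS.  ``entities`` may
    carry pre-computed NER output (e.g. from :func:`ingest_ner_xml`);
    otherwise the bundled lexicon tagger runs.  ``bold_dialect`` selects
    how bold compound-reference numbers are encoded in plain text:
    ``markdown`` (``**82**``), ``html`` (``<b>82</b>``) or ``positional``
    (a bare integer directly after a chemical entity, a compound/product
    noun or a yield verb, and not itself followed by a unit).
    """
    if bold_dialect not in BOLD_DIALECTS:
        raise ValueError(f"unknown bold dialect {bold_dialect!r}")
    lexicon = lexicon or default_lexicon()
    rules = rules or default_rules()
    if entities is None:
        entities = tag_chemicals(tokens, lexicon)

    tags: dict[int, tuple[str, TagNamespace]] = {}
    for ent in entities:
        for tid in ent.token_ids:
            tags.setdefault(tid, ("OSCAR-" + ent.type, TagNamespace.CHEM))

    for tok in tokens:
        if tok.id in tags:
            continue
        tag = rules.tag_for(tok.surface)
        if tag is not None:
            tags[tok.id] = (tag, TagNamespace.REGEX)

    if bold_dialect == "positional":
        for i, tok in enumerate(tokens):
            if tok.id in tags or not _INT_RE.match(tok.surface):
                continue
            prev = tokens[i - 1] if i > 0 else None
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            if prev is None:
                continue
            prev_tag = tags.get(prev.id, (None, None))[0]
            anchored = (
                (prev_tag or "").startswith("OSCAR-")
                or prev.surface.lower() in _REFERENCE_HOSTS
                or prev_tag == family_to_verb_tag("Yield")
            )
            next_is_unit = nxt is not None and tags.get(nxt.id, ("",))[0] in UNIT_TAGS
            if anchored and not next_is_unit:
                tags[tok.id] = ("CD-BOLD", TagNamespace.REGEX)

    out: list[TaggedToken] = []
    for tok in tokens:
        if tok.id in tags:
            tag, ns = tags[tok.id]
            out.append(TaggedToken(tok, tag, ns))
        else:
            out.append(TaggedToken(tok, pos_tag_word(tok.surface), TagNamespace.POS))
    return out
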