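"""Text normalisation, tokenisation and sentence segmentation.

Experimental chemistry prose mixes chemical names, bracketed data phrases
and ordinary English.  Before any tagging can happen the raw text is
normalised: nonprinting control characters are removed, line breaks become
plain spaces, and punctuation that has fused onto words (``"(0.63 g,"``) is
split apart — while decimal points inside numbers and the hyphens, commas
and brackets inside systematic chemical names (``2-nitrobenzene``,
``2,3-dihydro-[1H]-...``) are left intact.

All character offsets produced here (and inherited by every downstream
span) are 0-based half-open indices into the *original* raw string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "EmptyDocumentError",
    "RawDocument",
    "Token",
    "NormalizedText",
    "normalize_text",
    "tokenize",
    "split_sentences",
]

#: Code points stripped during normalisation (ASCII controls plus the
#: stray C1 controls that survive copy-paste from word processors).
NONPRINTING = frozenset(range(0, 32)) | frozenset({127, 129, 141, 143, 144, 157})

#: Tokens kept whole even though they contain internal punctuation.
PROTECTED_TOKENS = frozenset({"e.g.", "i.e.", "ca.", "etc.", "vs."})

#: Whole-chunk patterns kept intact: markdown/HTML bold compound references.
_PROTECTED_RE = re.compile(r"^(\*\*\d+\*\*|<b>\d+</b>)$")

_OPENERS = "([{'\"‘“"
_CLOSERS = ".,;:!?)]}'\"’”"

#: Punctuation that is always split out of a (non-chemical) chunk interior.
_SPLIT_CHARS = ",;()[]{}'\"‘’“”?!"


class EmptyDocumentError(ValueError):
    """Raised when a document is empty after normalisation."""


@dataclass(frozen=True)
class RawDocument:
    """A plain-text input document.

    ``source_id`` is an opaque caller-supplied identifier used in
    annotation files and diagnostics.
    """

    text: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise EmptyDocumentError("document text is empty")


@dataclass(frozen=True)
class Token:
    """A surface token with offsets into the original raw text."""

    surface: str
    start: int
    end: int
    id: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"token span [{self.start}, {self.end}) is empty")


@dataclass
class NormalizedText:
    """Normalised text plus the offset map back onto the raw input.

    ``pieces`` holds one ``(surface, raw_start, raw_end)`` triple per
    whitespace-delimited piece of ``text``, in order.
    """

    text: str
    raw: str
    pieces: list[tuple[str, int, int]] = field(default_factory=list)

    def to_raw(self, piece_index: int) -> tuple[int, int]:
        """Raw-text span of the ``piece_index``-th normalised piece."""
        _, start, end = self.pieces[piece_index]
        return start, end


def _is_chemical_candidate(core: str) -> bool:
    """Heuristic for systematic chemical-name morphology.

    A chunk whose interior commas/brackets must not be split: it carries
    locant morphology — digits plus hyphens plus a substantive letter run
    (``2,3-dihydro-[1H]-2-benzazepine``).  Plain data strings such as
    ``(0.63`` never satisfy this.
    """
    if "-" not in core or not re.search(r"\d", core):
        return False
    letters = re.sub(r"[^A-Za-z]", "", core)
    return len(letters) >= 4


def _split_core(core: list[tuple[str, int]]) -> list[list[tuple[str, int]]]:
    """Split a chunk core at punctuation, honouring decimals and names."""
    s = "".join(ch for ch, _ in core)
    if _is_chemical_candidate(s):
        return [core]
    out: list[list[tuple[str, int]]] = []
    cur: list[tuple[str, int]] = []
    n = len(core)
    for k in range(n):
        ch = core[k][0]
        if ch in _SPLIT_CHARS or ch in "%×*":
            if cur:
                out.append(cur)
                cur = []
            out.append([core[k]])
        elif ch == ".":
            prev_digit = k > 0 and core[k - 1][0].isdigit()
            next_digit = k + 1 < n and core[k + 1][0].isdigit()
            if prev_digit and next_digit:  # decimal point
                cur.append(core[k])
            else:
                if cur:
                    out.append(cur)
                    cur = []
                out.append([core[k]])
        elif ch == "°":
            # "80°C" -> "80", "°C": break before the degree sign only.
            if cur:
                out.append(cur)
                cur = []
            cur.append(core[k])
        else:
            cur.append(core[k])
    if cur:
        out.append(cur)
    return out


def _split_chunk(chunk: list[tuple[str, int]]) -> list[list[tuple[str, int]]]:
    s = "".join(ch for ch, _ in chunk)
    if s in PROTECTED_TOKENS or _PROTECTED_RE.match(s):
        return [chunk]
    tokens: list[list[tuple[str, int]]] = []
    i, j = 0, len(chunk)
    while i < j and chunk[i][0] in _OPENERS:
        tokens.append([chunk[i]])
        i += 1
    trailing: list[list[tuple[str, int]]] = []
    while j > i and chunk[j - 1][0] in _CLOSERS:
        trailing.insert(0, [chunk[j - 1]])
        j -= 1
    if i < j:
        tokens.extend(_split_core(chunk[i:j]))
    tokens.extend(trailing)
    return tokens


def normalize_text(raw: str) -> NormalizedText:
    """Normalise ``raw``: strip nonprinting characters, space out punctuation.

    Newlines, tabs and carriage returns delimit words and therefore become
    single spaces rather than being deleted outright; all other characters
    with code points in :data:`NONPRINTING` are removed.  Runs of
    whitespace collapse.  The returned object carries an offset map
    projecting every normalised piece back onto ``raw``.

    Raises :class:`EmptyDocumentError` if nothing survives normalisation.
    """
    cleaned: list[tuple[str, int]] = []
    for idx, ch in enumerate(raw):
        cp = ord(ch)
        if ch.isspace() or ch == " ":
            cleaned.append((" ", idx))
        elif cp in NONPRINTING:
            continue
        else:
            cleaned.append((ch, idx))

    # whitespace-delimited chunks, each a list of (char, raw_index)
    chunks: list[list[tuple[str, int]]] = []
    cur: list[tuple[str, int]] = []
    for ch, idx in cleaned:
        if ch == " ":
            if cur:
                chunks.append(cur)
                cur = []
        else:
            cur.append((ch, idx))
    if cur:
        chunks.append(cur)

    pieces: list[tuple[str, int, int]] = []
    for chunk in chunks:
        for tok in _split_chunk(chunk):
            surface = "".join(ch for ch, _ in tok)
            pieces.append((surface, tok[0][1], tok[-1][1] + 1))

    if not pieces:
        raise EmptyDocumentError("document is empty after normalisation")
    return NormalizedText(" ".join(p[0] for p in pieces), raw, pieces)


def tokenize(normalized: NormalizedText | str) -> list[Token]:
    """Whitespace-tokenise normalised text into ordered :class:`Token` s.

    Accepts either the :class:`NormalizedText` carrying the offset map
    (tokens then index the raw text) or a plain already-normalised string
    (offsets then index that string directly).  Empty input yields ``[]``.
    """
    if isinstance(normalized, str):
        if not normalized.strip():
            return []
        toks = []
        pos = 0
        for i, surf in enumerate(normalized.split()):
            start = normalized.index(surf, pos)
            toks.append(Token(surf, start, start + len(surf), i))
            pos = start + len(surf)
        return toks
    return [
        Token(surface, start, end, i)
        for i, (surface, start, end) in enumerate(normalized.pieces)
    ]


#: Full stops after these surfaces never end a sentence.
ABBREVIATIONS = frozenset({"ca", "etc", "vs", "approx", "fig", "eq", "no", "resp"})


def _starts_upper(tok: Token) -> bool:
    return tok.surface[0].isupper()


def split_sentences(tokens: list[Token]) -> list[list[Token]]:
    """Group ordered tokens into sentences.

    A boundary is placed after a full-stop token that does not follow a
    known abbreviation, and after a colon token (title lines of
    preparations end in a colon), whenever the next token starts with an
    upper-case letter or there is no next token.  Every token belongs to
    exactly one sentence.
    """
    sentences: list[list[Token]] = []
    cur: list[Token] = []
    for i, tok in enumerate(tokens):
        cur.append(tok)
        if tok.surface not in {".", ":"}:
            continue
        prev = tokens[i - 1].surface.lower() if i > 0 else ""
        if tok.surface == "." and prev in ABBREVIATIONS:
            continue
        nxt = tokens[i + 1] if i + 1 < len(tokens) else None
        if nxt is None or _starts_upper(nxt):
            sentences.append(cur)
            cur = []
    if cur:
        sentences.append(cur)
    return sentences
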