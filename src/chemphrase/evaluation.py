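"""Agreement metrics for phrase annotations.

Two annotators (human or machine) mark up the same procedure with action
phrases.  Agreement between their span lists is measured with a Dice
coefficient, ``s = 2|X ∩ Y| / (|X| + |Y|)``, where the intersection is
defined by a configurable match predicate:

* exact — surfaces are string-identical;
* filtered — identical after dropping stock words ('.', ',', ';', 'and',
  'to', 'the', 'a') and leading adverbs/prepositions;
* aligned — spans are first paired globally with the Needleman–Wunsch
  dynamic-programming algorithm (pair score = token-overlap Dice, gaps
  heavily penalised) and aligned pairs clearing a similarity threshold
  count as matches.

Alignment tolerates the boundary ambiguity inherent in phrase mark-up:
"to a 25 ml flask ..." and "a 25 ml flask ..." pair up even though an
exact or filtered match would reject them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import networkx as nx

from .preprocess import normalize_text, tokenize

__all__ = [
    "AnnotationSpan",
    "AnnotatorSet",
    "AlignmentScoring",
    "AlignmentResult",
    "AgreementReport",
    "dice",
    "exact_match",
    "filtered_match",
    "token_dice",
    "align_annotations",
    "aligned_agreement",
    "action_name_agreement",
    "agreement_matrix",
    "read_annotations",
    "write_annotations",
]

#: Stock words and tokens removed before filtered comparison.
STOCK_WORDS = frozenset({".", ",", ";", "and", "to", "the", "a"})

#: Words stripped from the front of a phrase (adverbs, prepositions,
#: relative markers) before filtered comparison.
LEADING_WORDS = frozenset(
    """in with by under at from between through into onto over after
    before during without on of as via upon within then subsequently
    which that while when and to""".split()
)


@dataclass(frozen=True)
class AnnotationSpan:
    """One phrase annotation: character span, surface text, action label."""

    start: int
    end: int
    surface: str
    label: str
    doc_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty span [{self.start}, {self.end})")


@dataclass
class AnnotatorSet:
    """One annotator's spans over a corpus, in document order."""

    annotator_id: str
    spans: list[AnnotationSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spans = sorted(
            self.spans, key=lambda s: (s.doc_id, s.start, s.end)
        )


@lru_cache(maxsize=4096)
def _tokens(surface: str) -> tuple[str, ...]:
    if not surface.strip():
        return ()
    return tuple(
        t.surface.lower() for t in tokenize(normalize_text(surface))
    )


def filtered_tokens(surface: str) -> tuple[str, ...]:
    """Tokens of a phrase after stock-word removal and leading-word strip."""
    toks = [t for t in _tokens(surface) if t not in STOCK_WORDS]
    while toks and toks[0] in LEADING_WORDS:
        toks.pop(0)
    return tuple(toks)


# ---------------------------------------------------------------------------
# match predicates and Dice

def exact_match(a: AnnotationSpan, b: AnnotationSpan) -> bool:
    """Strict agreement: the surfaces are string-identical."""
    return a.surface == b.surface


def filtered_match(a: AnnotationSpan, b: AnnotationSpan) -> bool:
    """Agreement up to stock words and leading adverbs/prepositions."""
    fa, fb = filtered_tokens(a.surface), filtered_tokens(b.surface)
    if not fa and not fb:
        return a.surface.strip().lower() == b.surface.strip().lower()
    return fa == fb


def token_dice(a: AnnotationSpan | str, b: AnnotationSpan | str) -> float:
    """Token-overlap Dice between two phrases (filtered token multisets)."""
    sa = a.surface if isinstance(a, AnnotationSpan) else a
    sb = b.surface if isinstance(b, AnnotationSpan) else b
    ta, tb = list(filtered_tokens(sa)), list(filtered_tokens(sb))
    if not ta and not tb:
        return 1.0
    common = 0
    pool = list(tb)
    for tok in ta:
        if tok in pool:
            pool.remove(tok)
            common += 1
    return 2.0 * common / (len(ta) + len(tb))


def dice(
    x: Sequence,
    y: Sequence,
    match: Callable[[object, object], bool],
) -> float:
    """Dice coefficient ``2|X∩Y| / (|X|+|Y|)`` under a match predicate.

    The intersection size is the maximum one-to-one matching between the
    two (multi)sets.  Two empty inputs have coefficient 1.0 by
    convention; one empty input scores 0.0.
    """
    if not x and not y:
        return 1.0
    if not x or not y:
        return 0.0
    graph = nx.Graph()
    graph.add_nodes_from(("a", i) for i in range(len(x)))
    graph.add_nodes_from(("b", j) for j in range(len(y)))
    for i, a in enumerate(x):
        for j, b in enumerate(y):
            if match(a, b):
                graph.add_edge(("a", i), ("b", j))
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    return 2.0 * len(matching) / (len(x) + len(y))


# ---------------------------------------------------------------------------
# Needleman–Wunsch alignment of annotation sequences

@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring for annotation alignment.

    Pair score is the token-overlap Dice of the two spans (in [0, 1]);
    gaps are heavily penalised relative to that scale.  Aligned pairs
    must clear ``match_threshold`` to count as agreement.
    """

    gap_penalty: float = -1.0
    match_threshold: float = 0.5
    similarity: Callable[[AnnotationSpan, AnnotationSpan], float] = token_dice


@dataclass
class AlignmentResult:
    """Column-wise alignment of two span sequences.

    ``index_map_a``/``index_map_b`` hold, per alignment column, the
    1-based index of the participating span on each side, or −1 for a
    gap.  ``pairs`` lists the matched columns as ``(i, j, similarity)``
    with 0-based indices; ``score`` is the optimal global-alignment
    score.
    """

    index_map_a: list[int]
    index_map_b: list[int]
    pairs: list[tuple[int, int, float]]
    score: float


def align_annotations(
    a: AnnotatorSet,
    b: AnnotatorSet,
    scoring: AlignmentScoring | None = None,
) -> AlignmentResult:
    """Globally align two annotators' span sequences (Needleman–Wunsch).

    Dynamic programming over the two sequences maximises the summed pair
    similarities minus gap penalties; the optimal alignment is order
    preserving.  Aligned pairs below the match threshold are reported as
    two unmatched columns rather than a pairing.
    """
    scoring = scoring or AlignmentScoring()
    xs, ys = a.spans, b.spans
    n, m = len(xs), len(ys)
    sim = [[scoring.similarity(xa, yb) for yb in ys] for xa in xs]

    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        score[i][0] = i * scoring.gap_penalty
        move[i][0] = 2
    for j in range(1, m + 1):
        score[0][j] = j * scoring.gap_penalty
        move[0][j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + sim[i - 1][j - 1]
            up = score[i - 1][j] + scoring.gap_penalty
            left = score[i][j - 1] + scoring.gap_penalty
            best = max(diag, up, left)
            score[i][j] = best
            move[i][j] = 1 if best == diag else (2 if best == up else 3)

    cols: list[tuple[int, int]] = []  # 0-based indices or -1
    i, j = n, m
    while i > 0 or j > 0:
        step = move[i][j]
        if step == 1:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif step == 2:
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, j - 1))
            j -= 1
    cols.reverse()

    map_a: list[int] = []
    map_b: list[int] = []
    pairs: list[tuple[int, int, float]] = []
    for ci, cj in cols:
        if ci >= 0 and cj >= 0 and sim[ci][cj] < scoring.match_threshold:
            # a forced pairing of dissimilar spans is no agreement
            map_a.append(ci + 1)
            map_b.append(-1)
            map_a.append(-1)
            map_b.append(cj + 1)
            continue
        map_a.append(ci + 1 if ci >= 0 else -1)
        map_b.append(cj + 1 if cj >= 0 else -1)
        if ci >= 0 and cj >= 0:
            pairs.append((ci, cj, sim[ci][cj]))
    return AlignmentResult(map_a, map_b, pairs, score[n][m])


def aligned_agreement(
    a: AnnotatorSet, b: AnnotatorSet, scoring: AlignmentScoring | None = None
) -> float:
    """Dice agreement (percent) with alignment-based intersection."""
    if not a.spans and not b.spans:
        return 100.0
    if not a.spans or not b.spans:
        return 0.0
    result = align_annotations(a, b, scoring)
    return 200.0 * len(result.pairs) / (len(a.spans) + len(b.spans))


def action_name_agreement(
    a: AnnotatorSet, b: AnnotatorSet, scoring: AlignmentScoring | None = None
) -> float:
    """Dice agreement (percent) on action labels over aligned pairs."""
    if not a.spans and not b.spans:
        return 100.0
    if not a.spans or not b.spans:
        return 0.0
    result = align_annotations(a, b, scoring)
    same = sum(
        1 for i, j, _ in result.pairs if a.spans[i].label == b.spans[j].label
    )
    return 200.0 * same / (len(a.spans) + len(b.spans))


# ---------------------------------------------------------------------------
# pairwise matrices

@dataclass
class AgreementReport:
    """Pairwise agreement matrix over annotators plus the machine."""

    ids: list[str]
    matrix: list[list[float | None]]
    machine_annotator_mean: float | None
    inter_annotator_mean: float

    def cell(self, id_a: str, id_b: str) -> float | None:
        return self.matrix[self.ids.index(id_a)][self.ids.index(id_b)]

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for i, row_id in enumerate(self.ids):
            cells = [
                "-" if v is None else f"{v:.1f}" for v in self.matrix[i]
            ]
            lines.append(row_id + "\t" + "\t".join(cells))
        if self.machine_annotator_mean is not None:
            lines.append(
                f"Machine-Annotator Agreement\t{self.machine_annotator_mean:.1f}"
            )
        lines.append(
            f"Inter-Annotator Agreement\t{self.inter_annotator_mean:.1f}"
        )
        return "\n".join(lines) + "\n"


def agreement_matrix(
    annotators: list[AnnotatorSet],
    machine: AnnotatorSet | None,
    metric: Callable[[AnnotatorSet, AnnotatorSet], float],
) -> AgreementReport:
    """Pairwise agreement matrix plus the two summary means.

    The machine-annotator mean averages the machine-vs-annotator cells;
    the inter-annotator mean averages the distinct annotator pairs.
    Fewer than two annotation sets in total is an error.
    """
    sets = list(annotators) + ([machine] if machine is not None else [])
    if len(sets) < 2:
        raise ValueError("need at least two annotation sets")
    k = len(sets)
    matrix: list[list[float | None]] = [[None] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            value = metric(sets[i], sets[j])
            matrix[i][j] = matrix[j][i] = value
    inter_cells = [
        matrix[i][j]
        for i in range(len(annotators))
        for j in range(i + 1, len(annotators))
    ]
    inter_mean = sum(inter_cells) / len(inter_cells) if inter_cells else 0.0
    machine_mean = None
    if machine is not None and annotators:
        mi = k - 1
        machine_mean = sum(matrix[mi][j] for j in range(len(annotators))) / len(
            annotators
        )
    return AgreementReport(
        [s.annotator_id for s in sets], matrix, machine_mean, inter_mean
    )


# ---------------------------------------------------------------------------
# annotation files

def write_annotations(annotator: AnnotatorSet, path) -> None:
    """Write spans as TSV (doc_id, start, end, label, surface) or JSON."""
    path = str(path)
    if path.endswith(".json"):
        payload = {
            "annotator_id": annotator.annotator_id,
            "spans": [
                {
                    "doc_id": s.doc_id,
                    "start": s.start,
                    "end": s.end,
                    "label": s.label,
                    "surface": s.surface,
                }
                for s in annotator.spans
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return
    with open(path, "w", encoding="utf-8") as fh:
        for s in annotator.spans:
            fh.write(
                f"{s.doc_id}\t{s.start}\t{s.end}\t{s.label}\t{s.surface}\n"
            )


def read_annotations(path, annotator_id: str | None = None) -> AnnotatorSet:
    """Read an annotation file written by :func:`write_annotations`."""
    path = str(path)
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        spans = [
            AnnotationSpan(
                start=s["start"],
                end=s["end"],
                surface=s["surface"],
                label=s["label"],
                doc_id=s.get("doc_id", ""),
            )
            for s in payload["spans"]
        ]
        return AnnotatorSet(annotator_id or payload["annotator_id"], spans)
    spans = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, start, end, label, surface = line.split("\t", 4)
            spans.append(
                AnnotationSpan(int(start), int(end), surface, label, doc_id)
            )
    return AnnotatorSet(annotator_id or path, spans)
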