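# Methods

This note documents the models, rules and numerical choices behind
`chemphrase`, the assumptions they rest on, and what the synthetic test
corpus does and does not demonstrate.

## Text normalisation and tokenisation

Normalisation removes the nonprinting code points {0–31, 127, 129, 141,
143, 144, 157}; newline, tab and carriage return are first replaced by a
single space (they delimit words — deleting them outright would fuse
words across line breaks). Spacing is then inserted between alphanumeric
and non-alphanumeric characters so that fused data strings such as
`"(0.63 g,"` break into their constituent tokens. Two protections apply:

* a decimal point flanked by digits stays inside its number;
* a whitespace chunk with locant morphology — at least one digit, at
  least one hyphen, and ≥ 4 letters (e.g. `2-nitrobenzene`,
  `5-Cyclobutyl-2,3-dihydro-[1H]-2-benzazepine`) — keeps its interior
  commas and brackets. This predicate is a heuristic: it deliberately
  excludes strings like `50-ml`, and it cannot recognise name-internal
  punctuation in names without digits (none arise in the bundled
  inputs).

A small protected-token list (`e.g.`, `i.e.`, `ca.`, `etc.`, `vs.`,
markdown/HTML bold references, `°C`) is kept whole. Normalisation is
idempotent, and every token carries 0-based half-open offsets into the
*raw* input, so downstream spans always project back to the original
text.

Sentence boundaries are placed after a full stop (not following a known
abbreviation) or a colon, when the next token starts with an upper-case
letter or the text ends. The colon rule exists because preparations are
headed by a title line ending in a colon; the capital-letter condition
is what protects decimal-free abbreviations, and it is the reason the
synthetic generator capitalises sentence-initial words.

## The tagging cascade

Tagging is total and exclusive: every token receives exactly one tag,
from the first of three stages that claims it.

1. **Chemical NER.** A phrase lexicon (longest match first, leftmost on
   ties; entries are tokenised with the same normaliser, so
   `N, N-dimethylformamide` matches across its internal comma) plus
   single-token morphology: spelled-out element names, molecular-formula
   strings (`MgSO4`, `EtOAc`), locant-hyphen names, the `poly-` prefix,
   and systematic suffixes (`-ol`, `-ene`, `-ate`, `-amide`, …) guarded
   by an English-word blocklist (so `state` and `mmol` are not
   compounds). Lexicon and morphology hits get confidence 1.0 —
   confidence is pass-through metadata, nothing downstream consumes it.
   Alternatively, pre-computed annotations in the `ne`-element XML
   dialect (attributes `id`, `surface`, `type` ∈ {CM, RN, ONT, CPR,
   ASE, CJ}, optional `confidence`) can be ingested and aligned to
   tokens by surface match; unalignable entities are logged and
   skipped.
2. **Domain regexes.** Ordered rules from a plain-TSV file: units
   (mass/molar/volume/percent/temperature/time), physical states,
   `mixture`/`solution`, bold compound references, and the action-verb
   lexicon (stem table with light suffix stemming: `-ed`, `-ing`,
   `-ies/-ied` → `-y`, doubled-consonant reduction, so
   `stirred/stirring → stir`). First matching rule wins.
3. **POS.** A bundled deterministic Penn tagger: a closed-class word
   list, punctuation mapping (`STOP`, `COMMA`, `LRB`, …), numerals →
   `CD`, then suffix defaults (`-ed` → VBD, `-ing` → VBG, `-ly` → RB,
   plural → NNS, else NN; hyphenated words → JJ). Any external tagger
   emitting Penn tags can replace it; the test suite pins the bundled
   one so assertions stay stable.

Bold compound references come in three configurable dialects, because
plain text has no typography: `**82**` (markdown), `<b>82</b>` (HTML),
and *positional* (default) — a bare integer directly after a chemical
entity, a compound/product noun or a yield verb, provided the next
token is not a unit (which would make it a measurement).

## Phrase grammar

The parser is recursive-descent with ordered choice and unbounded
lookahead (PEG-style backtracking), reflecting the observation that this
register almost always admits a single parse. Core productions:

    sentence    : (nounphrase | verbphrase | prepphrase | quantity | ...)*
    nounphrase  : DT? modifier* nounitem ((CC | COMMA) nounitem)*
    nounitem    : molecule | noun+ reference? quantity?
    molecule    : OSCAR+ reference? quantity?
    quantity    : LRB amount (COMMA amount)* RRB
    verbphrase  : TO? adv* verb+ (prepphrase | nounphrase | quantity)*
    prepphrase  : (IN | TO) (nounphrase | gerund | parenthetical)

Notable choices, each forced by attested constructions:

* **Quantity vs parenthetical.** A bracketed group is a quantity only if
  everything inside is numeric/unit material; brackets holding a
  chemical (`dried (MgSO4)`) parse as a parenthetical noun phrase.
  `5 × 50 cm3` becomes one volume with a repeat factor; a bare number in
  brackets is kept but flagged kind `unknown`; `ca.` survives as a
  qualifier.
* **Nominal action verbs.** After a determiner or adjective, an
  action-verb token may serve as a noun (`The precipitate was
  recovered`, `The organic extracts were dried`), so the verb tag does
  not spuriously open a verb phrase.
* **Gerund complements** are allowed after true prepositions only
  (`under stirring`, `without heating`) — after `to` they would swallow
  infinitives (`to give …`), which must start their own verb phrase.
* **Auxiliary-only guard.** A verb phrase consisting solely of
  auxiliaries with no complement is rejected, so junk like `the was to
  and` degrades into `Unmatched` nodes instead of a fake clause.
* **Error recovery** is skip-and-wrap: tokens matching no production
  accumulate into `Unmatched` nodes and parsing resynchronises; the
  parser never raises on sentence input, and the leaf-partition
  invariant (every token exactly once, in order) holds for every tree.

The preposition inventory extends beyond `to` to in/with/by/under/at/
between/…, required by role inference; the quantity grammar covers
volume, percent, temperature and time beyond the mass/molar pair.
Numbers are decimal-point only; comma decimals and scientific notation
are out of scope.

## Action phrases and roles

21 action families form a closed registry. Triggers are the first
action-tagged verb among a verb phrase's direct verb slots — a trigger
inside a prepositional complement names a condition, not a step. Each
triggered verb phrase opens an `ActionPhrase` that absorbs its subject
noun phrase and trailing material until a conjunction or the next
trigger; a bare-participle trigger inside an open action nests instead
of splitting (`… a solution of X dissolved in Y`). The trigger table is
an editable stem lexicon (one stem family per action, with common
synonyms such as afford/give/obtain → Yield, reflux → Heat); stemmed
matching covers inflected forms.

One implicit pattern is recognised without a verb: a molecule followed
by an `in`-prepositional phrase containing another molecule (typically
with a volume) is wrapped as a nested Dissolve phrase — this is how "the
sulfonamide 50 (…) in N,N-dimethylformamide (33 cm3)" inside an Add
step is understood as a dissolution whose solvent is the `in`-phrase
molecule.

Roles are assigned by three rules with fixed precedence (product >
solvent > reactant, strongest evidence first; each molecule occurrence
gets at most one role):

* **solvent** — molecule inside an `in`/`with` prepositional phrase
  within a Dissolve, Wash, Extract, Quench or Partition phrase (the set
  is configurable; nested implicit dissolves count);
* **reactant** — molecule carrying a compound-reference number within
  the first two sentences ("near the start" is operationalised as two
  sentences);
* **product** — the title-line compound (a leading segment ending in a
  colon), corroborated when a Yield phrase carries the same reference;
  also any referenced molecule inside a Yield phrase.

Preparations condense into a reactant→product digraph keyed by
reference numbers; product nodes carry the physical state (oil, solid,
gum, foam, crystals, else unknown) and a colour adjective captured
immediately before the state word in the Yield phrase's `as a …`
complement. Export formats: TSV node/edge lists and GraphML.

## XML dialect

Element names equal node labels, leaf text equals token surfaces, the
`type` attribute is written first for byte-stable output, encoding is
UTF-8. Serialisation refuses trees violating the leaf partition;
deserialisation rejects unknown element names. Round trips preserve
structure and surfaces but not character offsets (reloaded leaves get
synthetic consecutive offsets), which is what tree equality compares. A
RELAX NG schema is generated from the same label/tag registries the
parser uses, so schema and implementation cannot drift apart.

## Agreement methodology

The Dice coefficient `s = 2|X ∩ Y| / (|X| + |Y|)` is computed with the
intersection defined as a maximum one-to-one matching under the chosen
predicate (exact surface equality, or equality after dropping the stock
tokens '.', ',', ';', 'and', 'to', 'the', 'a' anywhere and
adverbs/prepositions at the phrase start). Conventions: two empty
annotation sets score 1.0, one empty set scores 0.0.

Alignment-based agreement runs Needleman–Wunsch over the two span
*sequences*: pair score = token-overlap Dice of the filtered token
multisets (in [0, 1]), gap penalty −1.0, traceback preferring the
diagonal on ties. A forced pairing of dissimilar spans (similarity
below the 0.5 match threshold) is reported as two unmatched columns.
All three constants are parameters of `AlignmentScoring`; the defaults
were chosen once on the scale argument (a gap must cost more than any
single pair can gain, and 0.5 separates "mostly the same phrase" from
"mostly different" under token Dice). The alignment result uses the
1-based column convention with −1 for gaps. Optimality is verified in
the tests against exhaustive enumeration of all monotone alignments for
instances up to 6 spans per side.

Action-name agreement applies Dice to aligned pairs with identical
labels (alignment-based pairing, since exact-span pairing collapses
under boundary noise). Pairwise matrices over any number of annotators
plus the machine report two summary means: the mean of machine-vs-
annotator cells and the mean of distinct annotator-pair cells.

## Synthetic corpus

The generator instantiates one sentence template per action family
(templates live in a TSV and can be extended without code changes) with
chemicals, solvents, quantities and conditions sampled from small fixed
pools; every sentence's gold span and label are recorded. Simulated
annotators perturb the gold spans — boundary jitter in whole words,
label confusion, and drops, each an independent per-span event — which
mimics the dominant disagreement modes between human annotators
(uncertain phrase boundaries, occasional type confusion, missed
phrases). A single seeded generator drives all sampling; identical
configurations reproduce identical corpora.

What passing tests show: the pipeline recovers the generating action
type for all 21 template families, the leaf partition holds over
hundreds of generated sentences, and the metric ordering aligned ≥
filtered ≥ exact emerges under realistic perturbation. What they do not
show: performance on real literature, whose vocabulary, clause
structure, anaphora and typography are far richer than the templates;
coverage there is bounded by the lexicon and the grammar fragment.

A separate grammar-level sampler draws small sentences directly from
the production rules while recording the derivation tree; the parser is
checked to reproduce the generating derivation exactly, which is the
round-trip evidence that the grammar and the parser implement the same
language.

## Problem sizes and runtime

The default verification runs use desk-scale inputs: 200 random
alignment instances (≤ 6 spans per side) against the brute-force
oracle, 500 generated sentences for the partition invariant, 80–100
sentences and 4 simulated annotators for the metric-ordering check.
These sizes give stable results in seconds on one CPU; all are
parameters, not limits.

## Known limitations

* The chemical lexicon is a compact curated set plus morphology; recall
  on unseen trivial names is limited by design (ingest external NER for
  production use). Morphology can overreach on rare English words
  ending in chemical suffixes; the blocklist covers common cases.
* Role inference is heuristic: unreferenced reagents remain unassigned
  (no stoichiometric or ontological reasoning), and anaphora across
  preparations is not resolved.
* The bundled POS tagger is intentionally simple; its errors are masked
  in-domain by the two earlier cascade stages.
* Whether Extract/Quench/Partition prepositional complements always
  name solvents is context-dependent; the action set for the solvent
  rule is therefore configurable.
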