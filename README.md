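# chemphrase

Phrase-based semantic parsing of chemical synthesis procedures.

Experimental sections of chemistry papers, theses and patents are written
in a highly formulaic register ("*Potassium carbonate (0.63 g, 4.56 mmol)
and thiophenol (0.19 g, 1.69 mmol) were added to the 2-nitrobenzene
sulfonamide …*"). `chemphrase` exploits that regularity to turn the prose
into structured, machine-readable data. It is aimed at text-mining and
cheminformatics work that needs reaction steps, amounts and compound
roles out of free text, without any trained model or external service.

## What it does

The pipeline runs five stages:

1. **Normalisation** — nonprinting characters are removed, line breaks
   become spaces, and fused punctuation is split (`"(0.63 g,"` →
   `"( 0.63 g ,"`) while decimal points and the hyphens/commas/brackets
   inside systematic chemical names are protected.
2. **Tokenisation and sentence splitting** — an adapted whitespace
   tokeniser; every offset points back into the raw text.
3. **Cascading tagging** — each token gets exactly one tag, from three
   namespaces tried in order: chemical named entities (lexicon phrases
   plus systematic-name morphology, or ingested `ne`-element XML from an
   external recogniser), domain regexes (action verbs → `VB-ADD` …,
   units → `NN-MASS`/`NN-MOLAR`/…, physical states, bold compound
   references → `CD-BOLD`), and finally Penn Treebank part-of-speech
   tags from a bundled deterministic tagger.
4. **Phrase parsing** — a recursive-descent, ordered-choice grammar with
   unbounded lookahead builds the phrase tree
   (`sentence → nounphrase verbphrase`, `molecule → OSCARCM+ quantity?`,
   `quantity → LRB mass COMMA molar RRB`, …). Unparseable stretches are
   wrapped in `Unmatched` nodes; the leaves always partition the
   sentence's tokens.
5. **Action and role labelling** — verb triggers map subtrees to one of
   21 closed action types (Add, ApparatusAction, Concentrate, Cool,
   Degass, Dissolve, Dry, Extract, Filter, Heat, Partition, Precipitate,
   Purify, Quench, Recover, Remove, Stir, Synthesize, Wait, Wash,
   Yield), with nesting for implicit dissolutions. Compound roles follow
   from context: solvents after "in"/"with" in dissolution-like phrases,
   reactants carrying a reference number near the start, the product
   from the title line and the Yield phrase. Preparations link into a
   reactant→product graph.

Trees serialise to an XML dialect (`ActionPhrase[@type]`, `NounPhrase`,
`MOLECULE`, `OSCAR-CM`, `VB-ADD`, …) and round-trip losslessly.

The `evaluation` module implements the span-agreement methodology used
to assess such parsers against human annotators: the Dice coefficient
`s = 2|X ∩ Y| / (|X| + |Y|)` with exact or stock-word-filtered string
matching, and a Needleman–Wunsch global alignment of the two annotation
sequences (pair score = token-overlap Dice, gaps penalised at −1,
matches counted above a 0.5 similarity threshold), which tolerates the
boundary ambiguity inherent in phrase mark-up. The `fixtures` module
generates synthetic gold-annotated paragraphs and simulated annotators
so every stage is testable offline.

## Worked example

```python
from chemphrase import parse_document
from chemphrase.samples import PREPARATION

doc = parse_document(PREPARATION)
for action in doc.actions:
    print(action.type.name, "-", action.surface[:40])
for role in doc.roles:
    print(role.role, "-", role.surface)
```

prints (abridged):

```
Add - Potassium carbonate ( 0.63 g , 4.56 mmol...
Stir - the mixture was stirred for 16 h .
Add - Deionised water ( 50 cm3 ) was added
Extract - the aqueous phase was extracted with et...
Dry - The organic extracts were dried ( MgSO4...
Concentrate - concentrated under reduced pressure
Yield - to give the title compound 82 ( 0.259 g...
product - 5-Cyclobutyl-2,3-dihydro-[1H]-2-benzazepine 82
reactant - 2-nitrobenzene sulfonamide 50 ( 0.50 g , 1.302 mmol )
solvent - N , N-dimethylformamide ( 33 cm3 )
solvent - ethyl acetate ( 5 × 50 cm3 )
```

Seven procedural steps are recognised; the quantities attached to each
compound (`0.63 g` / `4.56 mmol` for potassium carbonate, a `ca. 100%`
yield on the title compound) are available via
`doc.quantity_groups()`, and `build_reaction_graph([doc])` yields nodes
{50, 82} with the edge 50→82 and product state "oil".

The `examples/` directory holds one short narrative script per
capability (`parse_preparation.py`, `tag_to_xml.py`,
`annotation_agreement.py`, `synthetic_corpus.py`, `reaction_graph.py`);
each prints what it computes and says what the numbers mean. A thin CLI
mirrors the library: `chemphrase tag | evaluate | graph | fixtures`.

## Limitations

Rule-based by design: the chemical lexicon and morphology are a compact
curated set, not a statistical recogniser (pre-computed NER output can
be ingested instead); the grammar covers the procedural fragment of
chemistry English, not general syntax; machine-learning parsing,
name-to-structure resolution and CML export are out of scope. See
`docs/methods.md` for the model, parameter and design details.
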