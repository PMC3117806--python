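"""Bundled reference inputs used across tests, examples and docs.

A classic benzazepine preparation paragraph (title line plus three body
sentences, compound references written as bare integers after the
compound — the ``positional`` bold dialect), one canonical example
sentence per action family, and two annotators' phrase lists for a flask
assembly procedure used to demonstrate annotation alignment.
"""

from __future__ import annotations

__all__ = [
    "SAMPLE_SENTENCE",
    "PREPARATION_TITLE",
    "PREPARATION_PARAGRAPH",
    "PREPARATION",
    "ACTION_EXAMPLES",
    "ALIGNMENT_ANNOTATOR_A",
    "ALIGNMENT_ANNOTATOR_B",
]

#: The worked example sentence: two reagents added to a substrate.
SAMPLE_SENTENCE = (
    "Potassium carbonate (0.63 g, 4.56 mmol) and thiophenol "
    "(0.19 g, 1.69 mmol) were added to the 2-nitrobenzene sulfonamide."
)

PREPARATION_TITLE = "5-Cyclobutyl-2,3-dihydro-[1H]-2-benzazepine 82:"

PREPARATION_PARAGRAPH = (
    "Potassium carbonate (0.63 g, 4.56 mmol) and thiophenol (0.19 g, "
    "1.69 mmol) were added to the 2-nitrobenzene sulfonamide 50 (0.50 g, "
    "1.302 mmol) in N, N-dimethylformamide (33 cm3) at room temperature "
    "and the mixture was stirred for 16 h. Deionised water (50 cm3) was "
    "added and the aqueous phase was extracted with ethyl acetate "
    "(5 × 50 cm3). The organic extracts were dried (MgSO4) and "
    "concentrated under reduced pressure to give the title compound 82 "
    "(0.259 g, 1.302 mmol, ca. 100%) as an oil used without further "
    "purification."
)

#: Full preparation: title line then the procedure paragraph.
PREPARATION = PREPARATION_TITLE + "\n" + PREPARATION_PARAGRAPH

#: One canonical sentence per action family.
ACTION_EXAMPLES: dict[str, str] = {
    "Add": "Benzoyl peroxide (85 mg) was added to the solution.",
    "ApparatusAction": "A 50-ml round-bottom flask sealed with a septum.",
    "Concentrate": (
        "The filtrate was concentrated under reduced pressure without heating."
    ),
    "Cool": "The reaction was then cooled to rt.",
    "Degass": "The solution was purged with argon for 30 min.",
    "Dissolve": "Salt was dissolved in water.",
    "Dry": "The yellow product was dried under vacuum.",
    "Extract": "the products were extracted with diethyl ether (3 × 100 ml).",
    "Filter": "The solution was filtered through a short silica gel column.",
    "Heat": "The mixture was heated under reflux for 8 h.",
    "Partition": (
        "The reaction mixture was partitioned between H2O (100 ml) and "
        "EtOAc (400 ml)."
    ),
    "Precipitate": "Precipitating in methanol.",
    "Purify": "The mixture was purified by column chromatography.",
    "Quench": "The reaction was quenched with methanol.",
    "Recover": "The precipitate was recovered by filtration.",
    "Remove": "The solvent was removed under reduced pressure.",
    "Stir": "The reaction mixture was stirred at room temperature for 16 h.",
    "Synthesize": "Synthesis of aromatic polyethers by Scholl reaction.",
    "Wait": "The mixture was left 2d under stirring.",
    "Wash": "The resin was washed with DMF.",
    "Yield": (
        "Chromatography afforded the alcohol 10 as a colourless oil "
        "(88 mg, 70%)."
    ),
}

#: Two annotators' phrase lists over the same flask-assembly procedure;
#: annotator A marked five phrases, annotator B four (A's fourth has no
#: counterpart on B's side).
ALIGNMENT_ANNOTATOR_A = [
    "to a 25 ml three-necked round-bottomed flask fitted with a "
    "dean-stark trap, a condenser, and a nitrogen inlet/outlet and "
    "magnetic stirrer",
    "was subsequently sealed with a rubber septum",
    "stirring the reaction mixture overnight at room temperature",
    "evaporation of the eluate",
    "afforded 8 as a white solid (2.63 g, 57% yield)",
]

ALIGNMENT_ANNOTATOR_B = [
    "a 25 ml three-necked round-bottomed flask fitted with a dean-stark "
    "trap, a condenser, and a nitrogen inlet/outlet",
    "which was subsequently sealed with a rubber septum",
    "after stirring the reaction mixture overnight at room temperature",
    "which then afforded 8 as a white solid (2.63 g, 57% yield)",
]
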