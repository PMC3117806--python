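# Sentence templates, one canonical pattern per action family.
# Placeholders: {CM} chemical, {SOLV} solvent, {GAS} inert gas,
# {COLOUR} colour adjective, {STATE} physical state, {BOLD} compound
# reference, {N}/{N2} integers, {K} small count, {H} hours, {D} days,
# {PCT} percent yield.
Add	{CM} ({N} mg) was added to the solution.
ApparatusAction	A {N} ml round-bottom flask was sealed with a septum.
Concentrate	The filtrate was concentrated under reduced pressure.
Cool	The reaction was then cooled to rt.
Degass	The solution was purged with {GAS} for {N} min.
Dissolve	{CM} was dissolved in {SOLV}.
Dry	The {COLOUR} product was dried under vacuum.
Extract	The products were extracted with {SOLV} ({K} × {N} ml).
Filter	The solution was filtered through a short silica gel column.
Heat	The mixture was heated under reflux for {H} h.
Partition	The reaction mixture was partitioned between H2O ({N} ml) and EtOAc ({N2} ml).
Precipitate	Precipitating in {SOLV}.
Purify	The mixture was purified by column chromatography.
Quench	The reaction was quenched with {SOLV}.
Recover	The precipitate was recovered by filtration.
Remove	The solvent was removed under reduced pressure.
Stir	The reaction mixture was stirred at room temperature for {H} h.
Synthesize	Synthesis of {CM} by condensation polymerization.
Wait	The mixture was left {D}d under stirring.
Wash	The resin was washed with {SOLV}.
Yield	Chromatography afforded the {CM} {BOLD} as a {COLOUR} {STATE} ({N} mg, {PCT}%).
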