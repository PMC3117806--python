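# Action-verb lexicon: verb stem (or irregular form) <TAB> action family.
# Matching is stemmed: surface forms in -ed/-ing/-ies/-s reduce to these stems.
add	Add
charge	Add
seal	ApparatusAction
fit	ApparatusAction
equip	ApparatusAction
concentrate	Concentrate
evaporate	Concentrate
cool	Cool
chill	Cool
purge	Degass
degas	Degass
degass	Degass
sparge	Degass
dissolve	Dissolve
dry	Dry
dried	Dry
extract	Extract
filter	Filter
heat	Heat
reflux	Heat
warm	Heat
partition	Partition
precipitate	Precipitate
purify	Purify
quench	Quench
recover	Recover
remove	Remove
stir	Stir
synthesize	Synthesize
synthesise	Synthesize
synthesis	Synthesize
prepare	Synthesize
wait	Wait
left	Wait
stand	Wait
stood	Wait
wash	Wash
yield	Yield
afford	Yield
give	Yield
gave	Yield
obtain	Yield
furnish	Yield
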