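# Curated chemical lexicon: surface phrase <TAB> entity type
# Types: CM chemical compound, RN reaction name, ONT ontology term,
# CPR chemical prefix, ASE enzyme, CJ chemical adjective.
Potassium carbonate	CM
potassium carbonate	CM
thiophenol	CM
2-nitrobenzene sulfonamide	CM
N, N-dimethylformamide	CM
N,N-dimethylformamide	CM
dimethylformamide	CM
DMF	CM
water	CM
brine	CM
ethyl acetate	CM
EtOAc	CM
diethyl ether	CM
ether	CM
methanol	CM
ethanol	CM
isopropanol	CM
argon	CM
nitrogen	CM
benzoyl peroxide	CM
silica gel	CM
salt	CM
sodium chloride	CM
sodium hydroxide	CM
hydrochloric acid	CM
MgSO4	CM
Na2SO4	CM
H2O	CM
toluene	CM
hexane	CM
THF	CM
tetrahydrofuran	CM
dichloromethane	CM
DCM	CM
chloroform	CM
acetone	CM
acetonitrile	CM
alcohol	CM
benzene	CM
phenol	CM
aniline	CM
pyridine	CM
styrene	CM
methyl methacrylate	CM
vinyl chloride	CM
hydrolysis	RN
esterification	RN
polymerization	RN
polymerisation	RN
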