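# Regex tagger rules: anchored pattern over a whole token <TAB> tag.
# First matching rule wins; action-verb stems are checked before these.
^(g|mg|kg|µg|ug)$	NN-MASS
^(mol|mmol|µmol|umol|nmol)$	NN-MOLAR
^(mL|ml|L|l|cm3|dm3|µL|µl|uL|ul|litre|litres|liter|liters)$	NN-VOL
^%$	NN-PERCENT
^(°C|K)$	NN-TEMP
^(h|hr|hrs|hour|hours|min|mins|minute|minutes|s|sec|secs|second|seconds|d|day|days|overnight)$	NN-TIME
^[0-9]+(\.[0-9]+)?(h|d)$	NN-TIME
^(eq|equiv|equivalent|equivalents)$	NN-EQUIV
^(oil|oils|solid|solids|crystal|crystals|needle|needles|gum|foam|foams|powder|liquid|liquids|gas|gases)$	NN-STATE
^(mixture|mixtures)$	NN-MIXTURE
^(solution|solutions)$	NN-SOLUTION
^\*\*[0-9]+\*\*$	CD-BOLD
^<b>[0-9]+</b>$	CD-BOLD
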