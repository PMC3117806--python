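# Closed-class word list for the bundled deterministic POS tagger.
the	DT
a	DT
an	DT
this	DT
these	DT
those	DT
each	DT
and	CC
or	CC
plus	CC
nor	CC
to	TO
in	IN
with	IN
by	IN
under	IN
at	IN
from	IN
between	IN
through	IN
into	IN
onto	IN
over	IN
after	IN
before	IN
during	IN
without	IN
on	IN
of	IN
as	IN
via	IN
upon	IN
within	IN
was	VBD
were	VBD
is	VB
are	VB
be	VB
been	VB
being	VB
has	VB
have	VB
had	VB
not	RB
then	RB
subsequently	RB
slowly	RB
gradually	RB
finally	RB
also	RB
again	RB
once	RB
twice	RB
ca.	RB
e.g.	RB
i.e.	RB
etc.	RB
vs.	IN
which	WDT
it	PRP
further	JJ
room	NN
rt	NN
vacuum	NN
title	NN
yellow	JJ
white	JJ
colourless	JJ
colorless	JJ
red	JJ
brown	JJ
pale	JJ
dark	JJ
aqueous	JJ
organic	JJ
combined	JJ
reduced	JJ
saturated	JJ
anhydrous	JJ
deionised	JJ
deionized	JJ
distilled	JJ
magnetic	JJ
short	JJ
crude	JJ
resulting	JJ
remaining	JJ
excess	JJ
fresh	JJ
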