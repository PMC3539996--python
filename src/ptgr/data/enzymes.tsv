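# Type-II restriction enzymes shipped with the toolkit (REBASE-equivalent).
# cut_top / cut_bottom: 0-based offsets from the recognition start at which the
# top and bottom strands are cut (top-strand coordinates).
# name	recognition	cut_top	cut_bottom
XbaI	TCTAGA	1	5
SpeI	ACTAGT	1	5
NheI	GCTAGC	1	5
AvrII	CCTAGG	1	5
NdeI	CATATG	2	4
EcoRI	GAATTC	1	5
BamHI	GGATCC	1	5
BglII	AGATCT	1	5
SphI	GCATGC	5	1
PstI	CTGCAG	5	1
KpnI	GGTACC	5	1
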