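# Synthetic, illustrative codon-usage table in the style of a C. glutamicum
# preference profile (moderately GC-rich).  FIXTURE DATA: these frequencies
# are placeholders for testing the recoding machinery; supply a real usage
# table for production gene design.
# aa	codon	frequency
A	GCC	0.35
A	GCG	0.25
A	GCA	0.22
A	GCT	0.18
R	CGC	0.36
R	CGT	0.22
R	CGG	0.16
R	CGA	0.12
R	AGA	0.08
R	AGG	0.06
N	AAC	0.60
N	AAT	0.40
D	GAC	0.55
D	GAT	0.45
C	TGC	0.58
C	TGT	0.42
Q	CAG	0.62
Q	CAA	0.38
E	GAA	0.55
E	GAG	0.45
G	GGC	0.38
G	GGT	0.26
G	GGA	0.22
G	GGG	0.14
H	CAC	0.57
H	CAT	0.43
I	ATC	0.52
I	ATT	0.38
I	ATA	0.10
L	CTG	0.34
L	CTC	0.22
L	CTT	0.16
L	TTG	0.14
L	CTA	0.08
L	TTA	0.06
K	AAG	0.55
K	AAA	0.45
M	ATG	1.00
F	TTC	0.55
F	TTT	0.45
P	CCA	0.30
P	CCG	0.26
P	CCT	0.24
P	CCC	0.20
S	AGC	0.26
S	TCC	0.22
S	TCT	0.16
S	TCA	0.14
S	TCG	0.12
S	AGT	0.10
T	ACC	0.35
T	ACA	0.25
T	ACT	0.22
T	ACG	0.18
W	TGG	1.00
Y	TAC	0.56
Y	TAT	0.44
V	GTG	0.32
V	GTC	0.28
V	GTT	0.24
V	GTA	0.16
*	TAA	0.50
*	TGA	0.30
*	TAG	0.20
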