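# Tapinoma ibericum ON746721: codon counts over the 13 protein-coding genes
# (published codon-usage table; 3695 codons in total)
codon	amino_acid	n
UUU	F	368
UUC	F	18
UUA	L	443
UUG	L	13
CUU	L	31
CUC	L	2
CUA	L	29
CUG	L	0
AUU	I	490
AUC	I	22
AUA	M	347
AUG	M	23
GUU	V	63
GUC	V	7
GUA	V	45
GUG	V	4
UCU	S	116
UCC	S	11
UCA	S	98
UCG	S	1
CCU	P	54
CCC	P	12
CCA	P	51
CCG	P	4
ACU	T	64
ACC	T	4
ACA	T	58
ACG	T	1
GCU	A	50
GCC	A	3
GCA	A	21
GCG	A	1
UAU	Y	198
UAC	Y	20
UAA	*	13
UAG	*	0
CAU	H	47
CAC	H	15
CAA	Q	42
CAG	Q	2
AAU	N	220
AAC	N	17
AAA	K	112
AAG	K	6
GAU	D	48
GAC	D	12
GAA	E	62
GAG	E	7
UGU	C	31
UGC	C	3
UGA	W	80
UGG	W	2
CGU	R	15
CGC	R	0
CGA	R	25
CGG	R	3
AGU	S	20
AGC	S	4
AGA	S	75
AGG	S	13
GGU	G	25
GGC	G	8
GGA	G	89
GGG	G	27
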