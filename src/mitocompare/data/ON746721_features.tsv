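# Tapinoma ibericum mitogenome ON746721, published annotation table
# genome_length: 15715
# circular: true
# name: ON746721
Gene	Anticodon	Strand	Nucleotide Number	Start Codon	Stop Codon	IGN
(M) tRNA-Met	CAU	H	1–68			3
(I) tRNA-Ile	GAU	H	72–137			−3
(Q) tRNA-Gln	UUG	L	135–203			104
nad2		H	308–1291	ATA	TAA	1
(W) tRNA-Trp	UCA	H	1293–1366			32
(Y) tRNA-Tyr	GUA	L	1399–1467			56
(C) tRNA-Cys	GCA	L	1501–1567			21
cox1		H	1589–3118	ATG	TAA	0
(L1) tRNA-Leu	UAA	H	3119–3184			0
cox2		H	3185–3874	ATT	TAA	24
(K) tRNA-Lys	UUU	H	3899–3971			0
(D) tRNA-Asp	GUC	H	3972–4040			69
atp8		H	4041–4202	ATC	TAA	−7
atp6		H	4196–4864	ATG	TAA	6
cox3		H	4871–5653	ATG	TAA	74
(G) tRNA-Gly	UCC	H	5728–5795			0
nad3		H	5796–6146	ATA	TAA	37
(A) tRNA-Ala	UGC	H	6184–6256			22
(R) tRNA-Arg	UCG	H	6279–6354			16
(N) tRNA-Asn	GUU	H	6371–6439			31
(S1) tRNA-Ser	UCU	H	6471–6533			20
(E) tRNA-Glu	UUC	H	6554–6624			76
(F) tRNA-Phe	GAA	L	6701–6772			0
nad5		L	6773–8440	ATA	TAA	0
(H) tRNA-His	GUG	L	8441–8509			37
nad4		L	8547–9887	ATG	TAA	5
nad4l		L	9893–10,180	ATT	TAA	10
(T) tRNA-Thr	UGU	H	10,191–10,261			8
(P) tRNA-Pro	UGG	L	10,270–10,341			6
nad6		H	10,348–10,893	ATG	TAA	23
cob		H	10,917–12,038	ATG	TAA	10
(S2) tRNA-Ser	UGA	H	12,049–12,115			31
nad1		L	12,147–13,094	ATT	TAA	0
(L2) tRNA-Leu	UAG	L	13,095–13,166			0
lrRNA		L	13,167–14,511			0
(V) tRNA-Val	UAC	L	14,512–14,583			0
srRNA		L	14,584–15,374			0
Control Region			15,375–15,715
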