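group	chrom	pos	ref	alt	gene	aa_change	n_damaging	n_available	cosmic
Common	chr17	7578190	T	C	TP53	Y220C	7	7	COSM99720
Common	chr6	17781485	C	T	KIF13A	G1198S	6	7
Common	chr14	25044511	G	A	CTSG	R55*
Common	chr15	92459643	T	C	SLCO3A1	Y201H	6	7
Common	chr12	101880256	G	A	SPIC	E152K	2	7	COSM458288
Shared (P1, M)	chr10	28905209	T	G	WAC	L555*
Shared (P1, M)	chr14	24879362	G	T	NYNRIN	G788*
Shared (P1, M)	chr21	37710167	G	T	MORC3	G128V	6	7
Shared (P1, M)	chr1	154184966	C	G	C1orf43	D159H	6	7
Shared (P1, M)	chr4	154626187	A	G	TLR2	S710G	6	7
Shared (P1, M)	chr12	52183202	G	C	SCN8A	K1432N	6	7
Shared (P1, M)	chr14	23886761	G	C	MYH7	S1435C	6	6
Shared (P1, M)	chr1	11594572	G	A	PTCHD2	W1170*
Shared (P1, M)	chr12	20799431	C	A	PDE3A	N753K	6	7
Shared (P1, M)	chr2	196545035	G	T	SLC39A10	G90V	6	7
Cluster P1-specific	chr1	43317062	T	G	ZNF691	C176G	6	7
Cluster P1-specific	chr13	113893782	G	T	CUL4A	D318Y	6	7
Cluster P1-specific	chr6	117892084	C	A	GOPC	G276V	6	7
Cluster P1-specific	chr11	134090616	C	A	NCAPD3	W23C	6	7
Cluster M-specific	chr1	206944347	T	C	IL10	M95V	5	7
Cluster M-specific	chr2	242690697	C	G	D2HGDH	S345C	7	7
Cluster P2-specific	chr15	80866542	C	G	ARNT2	S457*
Cluster P2-specific	chr8	72211468	C	G	EYA1	D214H	7	7
Cluster P2-specific	chr3	101371645	T	G	ZBTB11	H816P	7	7
Cluster P2-specific	chr10	6528056	A	T	PRKCQ	C281S	7	7
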