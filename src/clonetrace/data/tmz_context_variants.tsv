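gene	chrom	pos	ref	alt	aa_change	base_change	context	tmz_emergent	source
EGFR	7	55241708	G	A	G719D	G>A	GCC-	0	GBM1_ex_vivo
EGFR	7	55249028	C	G	R776G	C>G	CCG+	0	GBM1_ex_vivo
FGFR1	8	38282211	G	A	S251F	G>A	TCC+	1	GBM1_ex_vivo
PTCH1	9	98268751	G	A	A111V	G>A	GCC+	1	GBM1_ex_vivo
BRCA2	13	32893288	G	A	E48K	G>A	TCT-	1	GBM1_ex_vivo
CDH1	16	68863600	C	T	P780L	C>T	CCT+	1	GBM1_ex_vivo
PTEN	10	89692972	T	TA	D153fs	T>TA		0	GBM1_ex_vivo
TP53	17	7579359	G	A	R110C	G>A	CCG+	1	GBM1_ex_vivo
TP53	17	7578406	C	T	R175H	C>T	GCG-	1	GBM1_ex_vivo
NF1	17	29667556	G	A	A2319T	G>A	GCT-	1	GBM1_ex_vivo
SMAD4	18	48604701	G	A	G508D	G>A	GCC-	1	GBM1_ex_vivo
MSH2	2	47709922	G	A	G880D	G>A	ACC-	1	GBM4-7_ex_vivo
CTNNB1	3	41266078	G	A	W25ter	G>A	GCC-	1	GBM4-7_ex_vivo
BAP1	3	52436821	C	T	E653K	C>T	TCC-	1	GBM4-7_ex_vivo
BAP1	3	52436887	C	T	E631K	C>T	TCC-	1	GBM4-7_ex_vivo
KDR	4	55946320	G	A	P1287S	G>A	GCC+	1	GBM4-7_ex_vivo
PIK3R1	5	67591097	A	G	N564D	A>G	TTC-	0	GBM4-7_ex_vivo
APC	5	112162897	G	A	A501T	G>A	GCA-	1	GBM4-7_ex_vivo
APC	5	112178024	C	T	P2245S	C>T	TCC+	1	GBM4-7_ex_vivo
EGFR	7	55220274	C	T	R222C	C>T	GCG+	0	GBM4-7_ex_vivo
EGFR	7	55221710	C	T	R252C	C>T	CCG+	0	GBM4-7_ex_vivo
EGFR	7	55221822	C	T	A289V	C>T	GCC+	0	GBM4-7_ex_vivo
TSC1	9	135779106	G	A	L714F	G>A	CCT+	1	GBM4-7_ex_vivo
PTEN	10	89653807	G	C	M35I	G>C	CCA-	0	GBM4-7_ex_vivo
PTPN11	12	112888189	G	A	E69K	G>A	TCC-	0	GBM4-7_ex_vivo
PTPN11	12	112926900	C	A	T511K	C>A	ACA+	0	GBM4-7_ex_vivo
TP53	17	7577524	GTGAGGATGG	G	P250del	GTGAGGATGG>G		0	GBM4-7_ex_vivo
TP53	17	7578236	A	C	Y205D	A>C	GTA+	1	GBM4-7_ex_vivo
NF1	17	29556257	G	A	G875D	G>A	ACC-	1	GBM4-7_ex_vivo
NF1	17	29667616	G	T	E2339ter	G>T	TCA-	0	GBM4-7_ex_vivo
NF1	17	29679366	C	T	R2517ter	C>T	CCG+	0	GBM4-7_ex_vivo
BRCA1	17	41223252	C	T	G1560E	C>T	TCC-	1	GBM4-7_ex_vivo
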