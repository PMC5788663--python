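sample_id	chrom	pos	ref	alt	gene	aa_change	consequence	vaf	alt_reads	depth	copy_number	context
GBM1-B Bulk	4	106196617	C	CCC	TET2	Q1652fs	frameshift	0.27			2	
GBM1-B Bulk	7	55241708	G	A	EGFR	G719D	missense	0.82			24	
GBM1-B P4	7	55241708	G	A	EGFR	G719D	missense	0.85			16	
GBM1-B P12	7	55241708	G	A	EGFR	G719D	missense	0.24			2.6	
SGS1-A Bulk	7	55241708	G	A	EGFR	G719D	missense	0.12			2.6	
SGS1-A P4	7	55241708	G	A	EGFR	G719D	missense	0.34			2.8	
SGS1-A P17	7	55241708	G	A	EGFR	G719D	missense	0.42			2.8	
SGS1-B Bulk	7	55241708	G	A	EGFR	G719D	missense	0.10			2.4	
SGS1-B P4	7	55241708	G	A	EGFR	G719D	missense	0.26			2.3	
SGS1-B P18	7	55241708	G	A	EGFR	G719D	missense	0.51			3	
SGS1-C Bulk	7	55241708	G	A	EGFR	G719D	missense	0.09			2	
SGS1-C P4	7	55241708	G	A	EGFR	G719D	missense	0.34			2.8	
SGS1-C P17	7	55241708	G	A	EGFR	G719D	missense	0.41			2.8	
GBM1-B Bulk	7	55249028	C	G	EGFR	R776G	missense	0.04			24	
GBM1-B P12	7	55249028	C	G	EGFR	R776G	missense	0.22			2.6	
GBM1-B Bulk	10	89692972	T	TA	PTEN	D153ins	frameshift	0.45			1	
GBM1-B P4	10	89692972	T	TA	PTEN	D153ins	frameshift	0.72			1	
GBM1-B P12	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-A Bulk	10	89692972	T	TA	PTEN	D153ins	frameshift	0.23			2	
SGS1-A P4	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-A P17	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-B Bulk	10	89692972	T	TA	PTEN	D153ins	frameshift	0.21			1.6	
SGS1-B P4	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-B P18	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-C P4	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-C P17	10	89692972	T	TA	PTEN	D153ins	frameshift	1.00			1	
SGS1-B P4	12	112926252	G	T	PTPN11	G466V	missense	0.23			2	
SGS1-A P4	16	68835663	T	C	CDH1	V85A	missense	0.17			2	
SGS1-C Bulk	17	7577121	G	A	TP53	R273C	missense	0.05			2	
SGS1-A Bulk	17	7578406	C	T	TP53	R175H	missense	0.23			2	
SGS1-A P4	17	7578406	C	T	TP53	R175H	missense	0.68			2	
SGS1-A P17	17	7578406	C	T	TP53	R175H	missense	0.52			2	
SGS1-B Bulk	17	7578406	C	T	TP53	R175H	missense	0.23			2	
SGS1-B P4	17	7578406	C	T	TP53	R175H	missense	0.80			2	
SGS1-B P18	17	7578406	C	T	TP53	R175H	missense	0.75			2	
SGS1-C P4	17	7578406	C	T	TP53	R175H	missense	0.67			2	
SGS1-C P17	17	7578406	C	T	TP53	R175H	missense	0.70			2	
SGS1-A Bulk	17	7579359	G	A	TP53	R110C	missense	0.10			2	
SGS1-A P4	17	7579359	G	A	TP53	R110C	missense	0.33			2	
SGS1-A P17	17	7579359	G	A	TP53	R110C	missense	0.48			2	
SGS1-B Bulk	17	7579359	G	A	TP53	R110C	missense	0.09			2	
SGS1-B P4	17	7579359	G	A	TP53	R110C	missense	0.20			2	
SGS1-B P18	17	7579359	G	A	TP53	R110C	missense	0.24			2	
SGS1-C P4	17	7579359	G	A	TP53	R110C	missense	0.33			2	
SGS1-C P17	17	7579359	G	A	TP53	R110C	missense	0.30			2	
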