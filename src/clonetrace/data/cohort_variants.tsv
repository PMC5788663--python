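sample_id	chrom	pos	ref	alt	gene	aa_change	consequence	vaf	alt_reads	depth	copy_number	context
PGS2 FFPE	3	178952085	A	G	PIK3CA	H1047R	missense	0.16			2	
GBM2 FFPE	10	89692847	T	C	PTEN	W111R	missense	0.75			1.4	
SGS2 Bulk	10	89692847	T	C	PTEN	W111R	missense	0.86			1.6	
SGS2 P3	10	89692847	T	C	PTEN	W111R	missense	1.00			2	
PGS1 FFPE	10	89711922	C	G	PTEN	Y180ter	nonsense	0.67			2.9	
GBM3 FFPE	13	48881540	A	AT	RB1	L88fs	frameshift	0.20			2	
SGS3 FFPE	13	48881540	A	AT	RB1	L88fs	frameshift	0.42			2	
PGS2 FFPE	13	48941669	A	T	RB1	L327ter	nonsense	0.13			2.7	
PGS1 FFPE	13	48955538	C	T	RB1	R552ter	nonsense	0.59			2	
PGS2 FFPE	17	7579472	G	C	TP53	P72R	missense	0.53			2	
PGS1 FFPE	17	7579464	G	A	TP53	P75S	missense	0.08			2	
PGS1 FFPE	17	7578406	C	T	TP53	R175H	missense	0.07			2	
GBM2 FFPE	17	7577584	TGGA	T	TP53	H233del	inframe	0.27			2	
SGS2 Bulk	17	7577584	TGGA	T	TP53	H233del	inframe	0.15			2	
SGS2 P3	17	7577584	TGGA	T	TP53	H233del	inframe	0.09			2	
PGS1 FFPE	17	7577550	C	G	TP53	G244A	missense	0.71			2	
GBM2 FFPE	17	7577548	C	T	TP53	G245S	missense	0.65			2	
SGS2 Bulk	17	7577548	C	T	TP53	G245S	missense	0.74			2	
SGS2 P3	17	7577548	C	T	TP53	G245S	missense	0.92			2	
GBM3 FFPE	17	7577548	C	A	TP53	G245V	missense	0.18			2	
SGS3 FFPE	17	7577548	C	A	TP53	G245V	missense	0.32			2	
PGS2 FFPE	17	7577121	G	A	TP53	R273C	missense	0.20			2	
GBM3 FFPE	17	7577082	C	T	TP53	E286K	missense	0.17			2	
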