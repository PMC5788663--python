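sample_id	patient_id	specimen	sector	passage	collection_day
PT01 Germline	PT01	germline			
GBM1-B Bulk	PT01	bulk	GBM1-B		0
GBM1-B P4	PT01	gliomasphere	GBM1-B	4	0
GBM1-B P12	PT01	gliomasphere	GBM1-B	12	0
SGS1-A Bulk	PT01	bulk	SGS1-A		188
SGS1-A P4	PT01	gliomasphere	SGS1-A	4	188
SGS1-A P17	PT01	gliomasphere	SGS1-A	17	188
SGS1-B Bulk	PT01	bulk	SGS1-B		188
SGS1-B P4	PT01	gliomasphere	SGS1-B	4	188
SGS1-B P18	PT01	gliomasphere	SGS1-B	18	188
SGS1-C Bulk	PT01	bulk	SGS1-C		188
SGS1-C P4	PT01	gliomasphere	SGS1-C	4	188
SGS1-C P17	PT01	gliomasphere	SGS1-C	17	188
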