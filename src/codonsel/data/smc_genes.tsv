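gene	complex	group	n_species	dnds
RAD21	cohesin	mitotic_cohesin	63	0.028
RAD21L1	cohesin	meiotic_cohesin	63	0.494
REC8	cohesin	meiotic_cohesin	63	0.267
SMC1A	cohesin	mitotic_cohesin	61	0.003
SMC1B	cohesin	meiotic_cohesin	60	0.215
SMC3	cohesin	mitotic_cohesin	63	0.001
PDS5A	cohesin	mitotic_cohesin	57	0.041
PDS5B	cohesin	mitotic_cohesin	60	0.036
STAG1	cohesin	mitotic_cohesin	63	0.013
STAG2	cohesin	mitotic_cohesin	63	0.016
STAG3	cohesin	meiotic_cohesin	63	0.225
NCAPD2	condensin	condensin	62	0.191
NCAPD3	condensin	condensin	63	0.275
NCAPG	condensin	condensin	63	0.258
NCAPG2	condensin	condensin	59	0.176
NCAPH	condensin	condensin	63	0.249
NCAPH2	condensin	condensin	62	0.229
SMC2	condensin	condensin	62	0.098
SMC4	condensin	condensin	61	0.127
NSMCE1	smc5_6	smc5_6	60	0.120
NSMCE2	smc5_6	smc5_6	63	0.158
NSMCE3	smc5_6	smc5_6	54	0.087
NSMCE4A	smc5_6	smc5_6	63	0.189
EID3	smc5_6	smc5_6	46	0.342
SMC5	smc5_6	smc5_6	63	0.131
SMC6	smc5_6	smc5_6	63	0.116
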