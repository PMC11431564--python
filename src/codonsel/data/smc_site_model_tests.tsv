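gene	comparison	freq_model	stat	p_printed
RAD21L1	M1a_vs_M2a	F3X4	102.59	5.28e-23
RAD21L1	M7_vs_M8	F3X4	113.97	1.79e-25
RAD21L1	M1a_vs_M2a	F61	92.78	7.13e-21
RAD21L1	M7_vs_M8	F61	108.91	2.25e-24
REC8	M1a_vs_M2a	F3X4	51.13	7.89e-12
REC8	M7_vs_M8	F3X4	88.22	6.97e-20
REC8	M1a_vs_M2a	F61	10.11	0.0064
REC8	M7_vs_M8	F61	50.28	1.21e-11
SMC1B	M1a_vs_M2a	F3X4	37.77	6.29e-9
SMC1B	M7_vs_M8	F3X4	105.04	1.55e-23
SMC1B	M1a_vs_M2a	F61	16.92	0.00021
SMC1B	M7_vs_M8	F61	55.29	9.85e-13
STAG3	M1a_vs_M2a	F3X4	27.39	1.13e-6
STAG3	M7_vs_M8	F3X4	79.88	4.51e-18
STAG3	M1a_vs_M2a	F61	18.02	0.00012
STAG3	M7_vs_M8	F61	58.44	2.04e-13
NCAPG	M1a_vs_M2a	F3X4	46.98	6.29e-11
NCAPG	M7_vs_M8	F3X4	90.97	1.76e-20
NCAPG	M1a_vs_M2a	F61	48.72	2.63e-11
NCAPG	M7_vs_M8	F61	102.35	5.96e-23
SMC5	M1a_vs_M2a	F3X4	17.97	0.000125
SMC5	M7_vs_M8	F3X4	61.40	4.65e-14
SMC5	M1a_vs_M2a	F61	7.91	0.019
SMC5	M7_vs_M8	F61	45.29	1.46e-10
NSMCE4A	M1a_vs_M2a	F3X4	33.96	4.22e-8
NSMCE4A	M7_vs_M8	F3X4	45.11	1.60e-10
NSMCE4A	M1a_vs_M2a	F61	22.82	1.11e-5
NSMCE4A	M7_vs_M8	F61	35.79	1.69e-8
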