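gene	site
RAD21L1	122
RAD21L1	148
RAD21L1	192
RAD21L1	284
RAD21L1	394
RAD21L1	398
RAD21L1	404
RAD21L1	411
RAD21L1	477
RAD21L1	433
REC8	152
REC8	168
REC8	191
REC8	199
REC8	253
REC8	264
REC8	269
REC8	358
REC8	400
REC8	449
REC8	178
REC8	244
SMC1B	6
SMC1B	18
SMC1B	251
SMC1B	491
SMC1B	877
SMC1B	1088
STAG3	24
STAG3	83
STAG3	86
STAG3	764
STAG3	862
STAG3	1044
STAG3	1089
STAG3	1154
STAG3	1159
STAG3	1197
NCAPG	36
NCAPG	37
NCAPG	84
NCAPG	616
SMC5	33
SMC5	38
SMC5	542
SMC5	797
NSMCE4A	14
NSMCE4A	185
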