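gene	branch	lnl_alt	lnl_null
STAU1	human	-4133.6	-4152.73
PSEN2	human	-4314.65	-4345.96
ANKK1	human	-6287.36	-6302.23
ETFDH	human	-4791.55	-4847.84
ZHX3	human	-7572.95	-7586.06
PCDH9	human	-6267.04	-6275.47
LYRM4	human	-381.331	-387.241
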