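17	37844392	37886915	ERBB2
7	55086724	55324313	EGFR
8	38268655	38326352	FGFR1
15	99192199	99507759	IGF1R
5	38475064	38608456	LIFR
17	47572654	47592382	NGFR
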