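# pwfrank validation-panel v1
gene	probe	microarray	qpcr	protein
CCR5	CCR5	2.17	1.85	down
CCR7	CCR7	-2.68	-2.70	down
CD206	MRC1	6.92	10.01	down
CD80	CD80	-1.80	-1.05	down
CD83	CD83	-4.63	-11.63	down
CD86	CD86	-1.28		down
CXCR4	CXCR4	-1.24	-2.7	down
IL10	IL10	-1.36	-2.10	up
IL12A	IL12A	-6.79	-11.1	down
IL12B	IL12B	-7.02	-39	down
IL6	IL6	-6.1	-21.9	down
MHCII_H2A	H2-Aa	1.29	6.03	down
MHCII_H2A	H2-Ab1	1.39	6.03	down
MHCII_H2E	H2-Eb1	1.31	15.23	down
MHCII_H2E	H2-Eb2	1.09	15.23	down
TM	THBD	1.17	3.06	up
TNFA	TNFA	-1.38	2.29	down
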