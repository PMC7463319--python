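code	n_clones	A	r	He	Ho	Fis
BBR	0	6.60	3.76	0.69	0.66	0.038
BGR	0	5.70	3.70	0.70	0.68	0.028
BRH	1	5.20	3.11	0.63	0.72	-0.15
BRS	4	3.10	2.11	0.42	0.50	-0.19
CCR	2	5.33	3.31	0.62	0.72	-0.16
CFR	0	4.70	2.95	0.55	0.53	0.042
CRS	0	5.00	3.25	0.63	0.65	-0.029
DDK	13	4.11	3.22	0.70	0.73	-0.042
DDW	0	4.80	3.25	0.62	0.60	0.033
DOB	0	5.20	3.24	0.67	0.71	-0.053
FLB	2	3.30	2.54	0.49	0.57	-0.152
GLT	0	5.00	3.07	0.61	0.63	-0.024
HDB	1	4.60	3.00	0.61	0.63	-0.031
HWK	0	4.30	2.85	0.56	0.60	-0.086
KAL	6	3.40	2.97	0.60	0.69	-0.168
MCL	10	4.30	2.94	0.64	0.65	-0.01
MOJ	0	4.00	2.66	0.59	0.62	-0.069
PDS	0	2.70	2.29	0.48	0.56	-0.204
PSE	0	4.60	3.24	0.55	0.48	0.139
SHF	1	6.70	3.67	0.72	0.71	0.011
SRT	0	4.70	3.58	0.68	0.70	-0.043
TRW	0	5.10	3.58	0.69	0.63	0.139
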