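code	latitude	longitude	n	census
BBR	-37.7433	144.0252	25	537
BGR	-38.2829	144.2974	25	50
BRH	-37.8183	141.8641	24	~25
BRS	-37.6107	144.2431	25	~80
CCR	-37.8328	143.6632	25	84
CFR	-37.4707	144.7220	25	25
CRS	-37.9485	142.5162	25	127
DDK	-38.0009	141.3377	24	100s
DDW	-37.8220	144.2021	25	>500
DOB	-37.3187	143.0507	24	114
FLB	-37.7022	143.5288	25	143
GLT	-37.7423	142.5517	24	>100
HDB	-37.5881	143.7231	26	69
HWK	-38.0753	142.3495	18	~1,300
KAL	-37.4622	143.5326	16	28
MCL	-38.1989	141.7394	21	100s
MOJ	-37.6641	142.2329	25	67
PDS	-37.9411	142.3761	5	15
PSE	-37.1557	144.6067	25	100s
SHF	-38.2367	142.0764	18	20
SRT	-37.6851	143.4078	22	22
TRW	-37.4596	143.5584	25	48
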