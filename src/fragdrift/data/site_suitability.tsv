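site	code	group	csi_current	csi_future	delta_csi_published
Bluebridge Road Elaine	BBR	fragmented	0.94	0.91	-3.2
Mt Duneed	BGR	fragmented	0.91	0.78	-14.3
Branxholme Railside	BRH	fragmented	0.97	0.68	-29.9
Ballan Railside	BRS	fragmented	0.95	0.92	-3.2
Cape Clear Rokewood Rd	CCR	fragmented	0.60	0.72	20.0
Clarkefield Railside	CFR	fragmented	0.87	0.81	-6.9
Caramut Roadside	CRS	fragmented	0.81	0.81	0.0
Drik Drik	DDK	fragmented	0.98	0.75	-23.5
Durdidwarrah	DDW	fragmented	0.94	0.92	-2.1
Dobie	DOB	fragmented	0.71	0.24	-66.2
Francis Lane	FLB	fragmented	0.80	0.86	7.5
Glenthompson	GLT	fragmented	0.89	0.90	1.1
Haddon	HDB	fragmented	0.91	0.89	-2.2
Hawkesdale/Coltons Road	HWK	fragmented	0.88	0.83	-5.7
Kayleys Lane	KAL	fragmented	0.85	0.77	-9.4
Mount Clay	MCL	fragmented	0.97	0.58	-40.2
Moutajup	MOJ	fragmented	0.98	0.86	-12.2
Purdeet Siding	PDS	fragmented	0.92	0.87	-5.4
Pastoria East	PSE	fragmented	0.76	0.30	-60.5
St Helens Flora Reserve	SHF	fragmented	0.82	0.63	-23.2
Skipton Rail Trail	SRT	fragmented	0.81	0.84	3.7
Trawalla East	TRW	fragmented	0.85	0.87	2.4
Durdidwarrah (unmodified)	DDW-U	unmodified	0.94	0.92	-2.1
Claude Austin Reserve	CAR	unmodified	0.96	0.12	-87.5
Victoria Valley	VVY	unmodified	0.97	0.82	-15.5
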