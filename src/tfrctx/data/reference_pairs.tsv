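tfr_locus	tfr_name	target_locus	target_product	separation_bp	regulation
SCO5082	ActR	SCO5083	ActA, MFS transporter	110	repressed
SGR3979	SGR3979	SGR3978	ABC transporter	144	repressed
SCO3367	SCO3367	SCO3366	MFS transporter	158	repressed
SGR5269	SGR5269	SGR5270	MFS transporter	212	none
SGR3402	SGR3402	SGR3403	MFS transporter	601	none
SCO4099	SCO4099	SCO4098	Acyltransferase, EC 2	139	repressed
SCO7222	SCO7222	SCO7223	Monooxygenase, EC 1	146	repressed
SGR6912	SGR6912	SGR6911	Glycosyl hydrolase, EC 3	280	none
SCO4118	AtrA	SCO4119	NADH dehydrogenase, EC 1	425	activated
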