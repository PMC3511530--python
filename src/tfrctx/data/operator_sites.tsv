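tfr	sequence
ActR	GAACGGGCCACCGTTT
ActR	CGCGACCACCGTTCCAT
ActR	AGAACGGTGGTCGTTCG
SGR3979	TGCGTAATGCTTACGCA
SGR3979	CGCGTATGGCATACGCA
SCO3367	ACTTGACGCCCGGCTAGT
SCO3367	ACTTGCCGGGCGGCAAGT
SGR5269	TTGCGCAGTGGGCAA
SGR5269	TTGCCCAGTGTGCAT
SCO4099	CACCTGTCGCACTAGTG
SCO7222	TGGAACGTCGTTCCA
SCO7222	TGGAACGACGTTCCA
SCO7222	TGGAACGCCGTTCCA
SGR6912	ACTAACCACTTAGT
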