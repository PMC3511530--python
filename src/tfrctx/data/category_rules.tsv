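pattern	match_kind	category	priority
MFS	keyword	MEMBRANE_TRANSPORTER:MFS	10
major facilitator	keyword	MEMBRANE_TRANSPORTER:MFS	11
MFS	name	MEMBRANE_TRANSPORTER:MFS	12
ABC	keyword	MEMBRANE_TRANSPORTER:ABC	20
ATP-binding cassette	keyword	MEMBRANE_TRANSPORTER:ABC	21
ABC_	name	MEMBRANE_TRANSPORTER:ABC	22
RND	keyword	MEMBRANE_TRANSPORTER:RND	30
resistance-nodulation	keyword	MEMBRANE_TRANSPORTER:RND	31
efflux	keyword	MEMBRANE_TRANSPORTER:other	40
transporter	keyword	MEMBRANE_TRANSPORTER:other	41
permease	keyword	MEMBRANE_TRANSPORTER:other	42
cl09931	accession	ENZYME:1	50
NADB_Rossmann	name	ENZYME:1	51
cl09933	accession	ENZYME:1	55
ACAD	name	ENZYME:1	56
EC 1	keyword	ENZYME:1	60
EC 2	keyword	ENZYME:2	61
EC 3	keyword	ENZYME:3	62
EC 4	keyword	ENZYME:4	63
EC 5	keyword	ENZYME:5	64
EC 6	keyword	ENZYME:6	65
oxidoreductase	keyword	ENZYME:1	70
dehydrogenase	keyword	ENZYME:1	71
monooxygenase	keyword	ENZYME:1	72
oxygenase	keyword	ENZYME:1	73
oxidase	keyword	ENZYME:1	74
reductase	keyword	ENZYME:1	75
transferase	keyword	ENZYME:2	80
kinase	keyword	ENZYME:2	81
synthase	keyword	ENZYME:2	82
hydrolase	keyword	ENZYME:3	85
protease	keyword	ENZYME:3	86
peptidase	keyword	ENZYME:3	87
esterase	keyword	ENZYME:3	88
nuclease	keyword	ENZYME:3	89
lyase	keyword	ENZYME:4	90
decarboxylase	keyword	ENZYME:4	91
dehydratase	keyword	ENZYME:4	92
isomerase	keyword	ENZYME:5	95
epimerase	keyword	ENZYME:5	96
ligase	keyword	ENZYME:6	97
synthetase	keyword	ENZYME:6	98
integral membrane protein	keyword	MEMBRANE_OTHER	100
transmembrane	keyword	MEMBRANE_OTHER	101
membrane protein	keyword	MEMBRANE_OTHER	102
transcriptional regulator	keyword	OTHER_PROTEIN	110
transcription factor	keyword	OTHER_PROTEIN	111
regulator	keyword	OTHER_PROTEIN	112
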