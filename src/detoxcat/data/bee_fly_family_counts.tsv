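family	subfamily	Bombus huntii	Bombus terrestris	Bombus impatiens	Apis mellifera	Megachile rotundata	Drosophila melanogaster
aldehyde dehydrogenase		5	5	5	6	18	23
catalase		2	1	2	6	5	3
cytochrome P450		44	50	49	46	52	85
cytochrome P450	CYP4	2	6	5	5	6	22
cytochrome P450	CYP6	18	22	22	28	19	22
glutaredoxin		2	3	7	4	3	7
peroxidase		16	9	9	17	9	20
superoxide dismutase		2	4	6	5	8	6
acyltransferase		13	28	30	32	8	55
glutathione S-transferase		11	14	15	18	9	42
glutathione S-transferase	sigma-GST	3	0	0	4	1	1
glutathione S-transferase	epsilon-GST	0	0	0	0	0	10
sulfotransferase		2	17	16	17	5	15
UDP-glucuronosyltransferase		2	6	8	2	2	7
acid/alkaline phosphatase		1	3	4	3	2	16
amidase		2	4	8	4	7	12
aminopeptidase		12	19	26	24	27	41
amylase		2	1	1	2	2	15
carboxylesterase/esterase		23	17	22	24	22	54
glycosidase		8	7	8	18	5	29
glucuronidase		1	1	1	1	2	4
glycosylase		3	2	5	7	6	5
nitrilase		25	1	2	3	2	2
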