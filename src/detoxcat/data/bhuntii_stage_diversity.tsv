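stage	oxidation_reduction	conjugation	hydrolysis	other	total
egg	36	14	22	21	93
early_instar	49	20	33	23	125
late_instar	64	18	35	12	129
pupa	31	9	13	7	60
adult_male	36	11	23	13	83
adult_worker	87	40	59	60	246
diapausing_queen	93	40	54	60	247
egglaying_queen	68	30	36	47	181
all_stages	202	109	143	130	584
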