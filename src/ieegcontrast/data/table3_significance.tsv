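structure	hemisphere	implanted	permutation	ml	mvpa
AMYGDALA	LH	2	2	0	1
AMYGDALA	RH	12	12	1	5
BANKSSTS	LH	10	10	3	5
BANKSSTS	RH	15	15	3	7
CAUDALANTERIORCINGULATE	RH	3	0	0	0
CAUDALMIDDLEFRONTAL	LH	22	22	1	3
CAUDALMIDDLEFRONTAL	RH	8	8	2	4
ENTORHINAL	RH	4	4	0	0
FUSIFORM	LH	25	25	3	13
FUSIFORM	RH	25	25	4	2
HIPPOCAMPUS	LH	8	0	0	3
HIPPOCAMPUS	RH	35	35	2	4
INFERIORPARIETAL	LH	17	17	1	14
INFERIORPARIETAL	RH	20	0	2	13
INFERIORTEMPORAL	LH	23	23	2	14
INFERIORTEMPORAL	RH	39	39	7	4
INSULA	LH	57	0	9	3
INSULA	RH	36	0	2	5
ISTHMUSCINGULATE	LH	8	0	1	1
ISTHMUSCINGULATE	RH	7	0	1	2
LATERALOCCIPITAL	LH	6	0	0	6
LATERALOCCIPITAL	RH	8	8	1	2
LATERALORBITOFRONTAL	LH	2	2	0	0
LATERALORBITOFRONTAL	RH	7	0	0	0
LINGUAL	LH	12	0	3	7
LINGUAL	RH	7	0	0	1
MEDIALORBITOFRONTAL	LH	3	0	1	0
MEDIALORBITOFRONTAL	RH	1	0	0	0
MIDDLETEMPORAL	LH	35	35	4	10
MIDDLETEMPORAL	RH	72	0	5	15
PARACENTRAL	LH	7	0	3	2
PARAHIPPOCAMPAL	LH	4	0	0	0
PARAHIPPOCAMPAL	RH	3	0	0	1
PARSOPERCULARIS	LH	30	0	4	4
PARSOPERCULARIS	RH	18	18	4	0
PARSORBITALIS	RH	6	0	1	0
PARSTRIANGULARIS	LH	6	6	2	0
PARSTRIANGULARIS	RH	4	0	1	0
POSTCENTRAL	LH	35	0	4	12
POSTCENTRAL	RH	17	17	1	8
POSTERIORCINGULATE	LH	9	0	0	2
PRECENTRAL	LH	44	44	3	15
PRECENTRAL	RH	18	0	3	4
PRECUNEUS	LH	17	17	0	9
PRECUNEUS	RH	8	8	0	4
ROSTRALANTERIORCINGULATE	LH	4	0	0	0
ROSTRALANTERIORCINGULATE	RH	3	0	0	0
ROSTRALMIDDLEFRONTAL	LH	18	0	2	3
ROSTRALMIDDLEFRONTAL	RH	11	0	0	3
SUPERIORFRONTAL	LH	43	0	6	7
SUPERIORFRONTAL	RH	5	0	0	2
SUPERIORPARIETAL	LH	6	6	0	1
SUPERIORPARIETAL	RH	10	10	2	9
SUPERIORTEMPORAL	LH	32	0	1	4
SUPERIORTEMPORAL	RH	26	0	2	6
SUPRAMARGINAL	LH	36	0	2	15
SUPRAMARGINAL	RH	33	33	3	19
TEMPORALPOLE	LH	2	0	0	0
TEMPORALPOLE	RH	6	0	0	1
TRANSVERSETEMPORAL	LH	8	0	0	3
TRANSVERSETEMPORAL	RH	6	0	0	1
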