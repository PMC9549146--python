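# Synthetic, approximate template-space (MNI-like, mm) centroids for
# Desikan-Killiany structures plus amygdala/hippocampus. Hand-constructed
# stand-ins used only to lay out simulated electrode trajectories and label
# volumes; NOT atlas-derived coordinates. LH mirrors RH with x negated.
structure	hemisphere	x	y	z
amygdala	LH	-24	-4	-18
amygdala	RH	24	-4	-18
bankssts	LH	-54	-46	10
bankssts	RH	54	-46	10
caudalanteriorcingulate	LH	-6	18	30
caudalanteriorcingulate	RH	6	18	30
caudalmiddlefrontal	LH	-38	12	44
caudalmiddlefrontal	RH	38	12	44
entorhinal	LH	-24	-8	-30
entorhinal	RH	24	-8	-30
fusiform	LH	-36	-44	-20
fusiform	RH	36	-44	-20
hippocampus	LH	-28	-24	-12
hippocampus	RH	28	-24	-12
inferiorparietal	LH	-42	-62	38
inferiorparietal	RH	42	-62	38
inferiortemporal	LH	-52	-44	-18
inferiortemporal	RH	52	-44	-18
insula	LH	-38	2	2
insula	RH	38	2	2
isthmuscingulate	LH	-8	-44	22
isthmuscingulate	RH	8	-44	22
lateraloccipital	LH	-30	-88	2
lateraloccipital	RH	30	-88	2
lateralorbitofrontal	LH	-26	32	-14
lateralorbitofrontal	RH	26	32	-14
lingual	LH	-14	-70	-6
lingual	RH	14	-70	-6
medialorbitofrontal	LH	-8	38	-16
medialorbitofrontal	RH	8	38	-16
middletemporal	LH	-58	-32	-8
middletemporal	RH	58	-32	-8
paracentral	LH	-8	-28	56
paracentral	RH	8	-28	56
parahippocampal	LH	-26	-32	-18
parahippocampal	RH	26	-32	-18
parsopercularis	LH	-48	14	12
parsopercularis	RH	48	14	12
parsorbitalis	LH	-44	40	-8
parsorbitalis	RH	44	40	-8
parstriangularis	LH	-48	30	8
parstriangularis	RH	48	30	8
postcentral	LH	-42	-26	50
postcentral	RH	42	-26	50
posteriorcingulate	LH	-6	-36	34
posteriorcingulate	RH	6	-36	34
precentral	LH	-40	-8	48
precentral	RH	40	-8	48
precuneus	LH	-10	-58	40
precuneus	RH	10	-58	40
rostralanteriorcingulate	LH	-6	36	12
rostralanteriorcingulate	RH	6	36	12
rostralmiddlefrontal	LH	-34	44	18
rostralmiddlefrontal	RH	34	44	18
superiorfrontal	LH	-12	28	48
superiorfrontal	RH	12	28	48
superiorparietal	LH	-24	-60	54
superiorparietal	RH	24	-60	54
superiortemporal	LH	-54	-20	4
superiortemporal	RH	54	-20	4
supramarginal	LH	-54	-42	32
supramarginal	RH	54	-42	32
temporalpole	LH	-34	12	-34
temporalpole	RH	34	12	-34
transversetemporal	LH	-46	-22	10
transversetemporal	RH	46	-22	10
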