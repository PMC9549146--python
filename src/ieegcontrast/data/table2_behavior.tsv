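subject	angry_trials	happy_trials	angry_rt_s	happy_rt_s	rt_p
SEEG85	45	21	0.92	0.62	0.0000
SEEG88	62	66	0.96	0.84	0.0000
SEEG89	47	58	0.97	0.85	0.0000
SEEG90	56	60	0.91	0.83	0.0117
SEEG92	53	55	0.95	0.90	0.1700
SEEG94	59	61	0.92	0.87	0.0903
SEEG96	45	54	0.97	0.75	0.0000
SEEG97	56	63	0.98	0.88	0.0005
SEEG98	58	57	0.90	0.88	0.3135
SEEG99	59	61	0.89	0.85	0.2466
SEEG101	43	53	1.05	0.84	0.0000
SEEG102	36	45	1.19	1.10	0.0216
SEEG104	51	56	0.97	0.81	0.0000
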