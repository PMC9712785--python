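feature_id	log2fc	p_value	regulation
miR-33-5p	1.059582	0.028052	Up
miR-3470b	1.121627	0.01195	Up
miR-3963	1.120086	0.031801	Up
miR-466i-5p	1.685278	0.001582	Up
miR-490-5p	1.036711	0.018928	Up
miR-511-3p	1.199429	0.011024	Up
miR-5121	4.467184	9.38E-09	Up
miR-6240	1.683446	0.009093	Up
miR-669f-5p	1.835861	0.044532	Up
miR-1839-3p	-1.68766	0.034451	Down
miR-1964-3p	-1.35741	0.037749	Down
miR-1969	-2.56641	0.008142	Down
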