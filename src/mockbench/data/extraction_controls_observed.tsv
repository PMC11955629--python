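lineage	R1P1Zymoex	R1P2Zymoex	R1P3Zymoex	R1P4Zymoex	R2P1Zymoex	R2P2Zymoex	R2P3Zymoex
g__Limosilactobacillus;s__fermentum	18.21	18.27	17.99	17.64	18.60	16.60	18.02
g__Bacillus;s__subtilis	0.00	19.55	19.71	0.00	18.76	17.63	18.55
g__Staphylococcus;s__aureus	10.82	9.13	9.13	11.47	10.96	9.31	10.75
g__Listeria;s__monocytogenes	4.41	4.47	4.59	4.97	0.00	4.58	4.67
g__Salmonella;s__enterica	17.58	18.90	17.61	16.37	10.95	20.39	19.22
g__Escherichia/Shigella;s__coli	17.06	18.29	18.26	18.89	20.57	19.26	20.50
g__Enterococcus;s__faecalis	5.39	4.53	4.53	5.28	5.36	4.96	4.81
g__Pseudomonas;s__aeruginosa	7.37	6.52	7.77	4.50	4.63	7.25	3.40
k__;p__;c__;o__;f__;g__;s__	19.16	0.34	0.42	20.89	10.18	0.02	0.09
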