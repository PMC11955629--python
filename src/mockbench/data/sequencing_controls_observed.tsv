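lineage	R1P1Zymoseq	R1P2Zymoseq	R1P3Zymoseq	R1P4Zymoseq	R2P1Zymoseq	R2P2Zymoseq	R2P3Zymoseq
g__Limosilactobacillus;s__fermentum	13.08	12.60	13.32	11.94	13.88	13.16	12.86
g__Bacillus;s__subtilis	17.89	17.84	0.00	17.05	17.81	0.00	17.99
g__Staphylococcus;s__aureus	13.84	13.34	13.83	14.04	13.95	14.22	14.03
g__Listeria;s__monocytogenes	15.27	14.76	14.54	15.41	15.85	15.95	16.05
g__Salmonella;s__enterica	11.49	12.04	13.12	6.32	0.01	11.23	9.06
g__Escherichia/Shigella;s__coli	11.59	12.40	10.84	11.62	12.18	11.20	11.64
g__Enterococcus;s__faecalis	11.98	11.18	11.50	11.12	11.89	12.40	11.76
g__Pseudomonas;s__aeruginosa	4.44	5.10	4.64	4.94	3.72	4.09	3.39
k__;p__;c__;o__;f__;g__;s__	0.42	0.74	18.20	7.54	10.72	17.74	3.21
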