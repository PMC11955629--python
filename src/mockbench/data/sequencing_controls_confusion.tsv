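measure	R1P1Zymoseq	R1P2Zymoseq	R1P3Zymoseq	R1P4Zymoseq	R2P1Zymoseq	R2P2Zymoseq	R2P3Zymoseq
true_positives	8	8	7	8	8	7	8
false_positives	4	8	4	6	1	0	3
false_negatives	0	0	1	0	0	1	0
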