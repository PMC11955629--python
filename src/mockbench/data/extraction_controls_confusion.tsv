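measure	R1P1Zymoex	R1P2Zymoex	R1P3Zymoex	R1P4Zymoex	R2P1Zymoex	R2P2Zymoex	R2P3Zymoex
true_positives	7	8	8	7	7	8	8
false_positives	15	3	3	0	3	0	2
false_negatives	1	0	0	1	1	0	0
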