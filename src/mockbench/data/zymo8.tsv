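species	theoretical_percent
Limosilactobacillus fermentum	18.4
Bacillus subtilis	17.4
Staphylococcus aureus	15.5
Listeria monocytogenes	14.1
Salmonella enterica	10.4
Escherichia/Shigella coli	10.1
Enterococcus faecalis	9.9
Pseudomonas aeruginosa	4.2
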