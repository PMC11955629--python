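# Catalogue of plausible low-abundance spurious species used by the
# synthetic generator: common skin, oral, environmental and reagent taxa.
Cutibacterium acnes
Corynebacterium tuberculostearicum
Streptococcus mitis
Streptococcus salivarius
Rothia mucilaginosa
Micrococcus luteus
Acinetobacter johnsonii
Acinetobacter lwoffii
Moraxella osloensis
Bradyrhizobium japonicum
Methylobacterium radiotolerans
Sphingomonas paucimobilis
Ralstonia pickettii
Burkholderia cepacia
Pelomonas puraquae
Herbaspirillum seropedicae
Delftia acidovorans
Comamonas testosteroni
Stenotrophomonas maltophilia
Pseudomonas fluorescens
Janthinobacterium lividum
Massilia timonae
Curvibacter lanceolatus
Aquabacterium parvum
Undibacterium pigrum
Caulobacter vibrioides
Brevundimonas diminuta
Ochrobactrum anthropi
Phyllobacterium myrsinacearum
Mesorhizobium loti
Novosphingobium resinovorum
Sphingobium yanoikuyae
Deinococcus radiodurans
Thermus thermophilus
Anoxybacillus flavithermus
Geobacillus stearothermophilus
Paenibacillus glucanolyticus
Brevibacillus agri
Lysinibacillus sphaericus
Sporosarcina psychrophila
Kocuria rhizophila
Dermacoccus nishinomiyaensis
Brachybacterium conglomeratum
Janibacter limosus
Dietzia maris
Gordonia terrae
Tsukamurella paurometabola
Williamsia muralis
Nocardioides albus
Aeromicrobium erythreum
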