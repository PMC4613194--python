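# Clone-library category counts from a published clone-library survey of
# endosymbiont 16S rRNA sequences across 12 Lachninae aphid samples
# (185 positive clones in total; 12 chimeric).
category	count
Buchnera	99
Serratia	58
Wolbachia	1
Arsenophonus	5
Sodalis-like	9
Regiella	1
chimera	12
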