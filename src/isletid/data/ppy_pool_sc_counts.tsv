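# Scored-cell counts for the pooled Ppy+ population of the mouse islet
# single-cell dataset: monohormonal Ppy cells and the three Ppy-anchored
# bihormonal subtypes retained in the hybrid cluster. The four categories
# partition the Ppy+ pool (denominator = pool size).
unit	category	numerator	denominator
sc_pooled	Ppy	1167	1730
sc_pooled	Ppy+Gcg	415	1730
sc_pooled	Ppy+Sst	84	1730
sc_pooled	Ppy+Ins2	64	1730
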