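# Published overlap counts between the genes upregulated in each bihormonal
# population (vs monohormonal Ppy/PPY cells) and the partner type's identity
# (ID) gene set. n_up is the size of the upregulated list where published;
# blank where only the overlap and ID-set size were printed.
comparison	species	n_overlap	n_id	n_up
Ppy+Gcg_vs_alphaID	mouse	77	82	199
Ppy+Sst_vs_deltaID	mouse	6	9
Ppy+Ins2_vs_betaID	mouse	35	134
PPY+GCG_vs_alphaID	human	26	99	70
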