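# Scored-cell counts for lineage-traced gamma-cells that engaged insulin
# production after massive beta-cell ablation: cells with no detectable Ppy
# among all insulin+ traced cells (pooled over 4 animals; per-animal counts
# were not published).
unit	category	numerator	denominator
pooled	Ins+YFP+Ppy-	103	108
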