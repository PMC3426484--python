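statistic	part	n_genes	n_events
FST	upstream	25	0
FST	downstream	21	7
ABS_IHS	upstream	25	4
ABS_IHS	downstream	21	8
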