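statistic	centrality	n1	n2	rank_sum_1	rank_sum_2	u	z	p_level
ABS_IHS	Betweenness	40	17	1151.00	502.00	331.00	-0.16	0.8749
ABS_IHS	Centroid	40	17	1201.50	451.50	298.50	0.73	0.4674
ABS_IHS	Closeness	40	17	1173.50	479.50	326.50	0.24	0.8135
ABS_IHS	Eccentricity	40	17	1157.00	496.00	337.00	-0.05	0.9578
ABS_IHS	Node Degree	40	17	1183.50	469.50	316.50	0.42	0.6758
FST	Betweenness	47	10	1425.50	227.50	172.50	1.32	0.1885
FST	Centroid	47	10	1357.50	295.50	229.50	-0.12	0.9078
FST	Closeness	47	10	1404.50	248.50	193.50	0.87	0.3830
FST	Eccentricity	47	10	1485.00	168.00	113.00	2.59	0.0097
FST	Node Degree	47	10	1254.00	399.00	126.00	-2.33	0.0196
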