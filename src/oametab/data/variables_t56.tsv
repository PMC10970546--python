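# VIP-selected variables, paired T0 vs T56 comparison (feature id is "mz;rt")
feature_id	mz	rt	polarity	vip
203.2846;6.00	203.2846	6.00	neg	1.41
231.0456;1.12	231.0456	1.12	neg	0.66
279.0362;0.80	279.0362	0.80	neg	0.39
251.1023;4.46	251.1023	4.46	pos	0.12
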