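# VIP-selected variables, paired T0 vs T28 comparison (feature id is "mz;rt")
feature_id	mz	rt	polarity	vip
377.1360487;8.543	377.1360487	8.543	pos	5.547
103.0543706;1.108	103.0543706	1.108	pos	4.738
395.1254806;8.062	395.1254806	8.062	pos	4.337
166.0864745;1.108	166.0864745	1.108	pos	4.189
120.0810237;1.109	120.0810237	1.109	pos	3.800
220.1461317;1.105	220.1461317	1.105	pos	2.808
171.9808059;0.632	171.9808059	0.632	pos	2.491
1145.217439;9.503	1145.217439	9.503	pos	2.402
352.3057184;8.762	352.3057184	8.762	pos	2.314
529.3525685;9.107	529.3525685	9.107	pos	2.292
148.0038081;0.632	148.0038081	0.632	pos	2.127
1274.179758;9.5	1274.179758	9.5	pos	2.112
335.2787707;8.765	335.2787707	8.765	pos	2.046
1307.668417;9.502	1307.668417	9.502	pos	1.990
1200.745803;0.579	1200.745803	0.579	pos	1.957
541.3706018;8.817	541.3706018	8.817	pos	1.926
1423.929102;9.5	1423.929102	9.5	pos	1.921
1240.189772;9.501	1240.189772	9.501	pos	1.905
1239.680395;9.501	1239.680395	9.501	pos	1.890
1501.870123;9.502	1501.870123	9.502	pos	1.877
1429.869007;9.499	1429.869007	9.499	pos	1.860
126.0220994;0.635	126.0220994	0.635	pos	1.695
1173.204232;9.499	1173.204232	9.499	pos	1.584
1208.700279;9.501	1208.700279	9.501	pos	1.575
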