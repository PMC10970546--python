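# VIP-selected variables, paired T0 vs T84 comparison (feature id is "mz;rt")
feature_id	mz	rt	polarity	vip
595.4212;9.168	595.4212	9.168	pos	2.269
573.4081;9.183	573.4081	9.183	pos	2.266
551.3949;9.198	551.3949	9.198	pos	2.232
617.4344;9.154	617.4344	9.154	pos	2.226
529.3819;9.213	529.3819	9.213	pos	2.139
639.4473;9.141	639.4473	9.141	pos	2.118
661.4605;9.126	661.4605	9.126	pos	2.019
507.3685;9.229	507.3685	9.229	pos	2.001
683.4734;9.113	683.4734	9.113	pos	1.87
485.3556;9.245	485.3556	9.245	pos	1.822
705.4863;9.100	705.4863	9.100	pos	1.662
463.3419;9.260	463.3419	9.260	pos	1.548
820.5975;9.294	820.5975	9.294	pos	1.427
727.4989;9.087	727.4989	9.087	pos	1.34
274.2747;7.486	274.2747	7.486	pos	1.326
437.2907;7.905	437.2907	7.905	neg	1.775
391.2852;7.905	391.2852	7.905	neg	1.822
391.2125;6.377	391.2125	6.377	neg	1.715
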