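chr	start	end	ref	alt	location	gene	fraction	depth	validated	appearance
12	33958549	33958549	T	C	exonic	Twist1	0.4375	16	Yes	Yes
12	55089706	55089706	T	C	intronic	Srp54a	0.5714	7	Yes	No
12	72775180	72775180	C	T	intronic	Ppm1a	0.5714	7	Yes	No
12	77451898	77451898	T	C	intronic	Fut8	0.4713	244	Yes	No
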