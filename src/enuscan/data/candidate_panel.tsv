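variant	A1	A2	A3	A4	A5	A6	A7	U1	U2	U3	U4	U5
phenotype	Aff	Aff	Aff	Aff	Aff	Aff	Aff	Unaff	Unaff	Unaff	Unaff	Unaff
Adgrb3	?	?	?	?	?	+	?	−	?	+	?	?
Fam205a1	+	−	?	?	−	+	?	+	−	−	?	?
Lcorl	?	?	?	?	+	+	?	+	+	+	?	?
Oas3	?	?	?	?	+	+	?	+	−	+	?	?
Amz1	?	?	?	?	−	+	?	+	−	−	?	?
Il17ra	−	?	?	?	?	+	?	−	?	−	?	?
Hemk1	−	−	+	−	−	+	?	−	?	+	?	?
Fbxw21	?	?	?	?	−	+	?	+	+	−	?	?
Xirp1	?	?	?	?	?	+	?	+	+	+	?	?
Slc18b1	?	?	?	?	?	+	?	+	+	+	?	?
Twist1	+	+	+	+	+	+	+	−	−	−	−	−
Foxa1	+	−	−	?	?	+	?	−	?	−	?	?
Pcdhb22	−	+	?	?	−	+	?	+	−	−	?	?
Hebp1	?	?	+	?	?	?	?	-	?	−	+	?
Herc2	?	?	?	?	?	+	?	+	?	?	?	?
Tmprss15	?	?	?	?	?	−	?	?	?	?	?	?
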