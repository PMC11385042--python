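statistic	key	expected
richness	s1	2
richness	s2	2
richness	s3	3
richness	s4	3
richness	s5	3
richness	s6	3
shannon	s1	0.6931471805599453
shannon	s2	0.6931471805599453
shannon	s3	1.0549201679861442
bray_curtis	s1,s2	0.0
bray_curtis	s1,s3	0.2
bray_curtis	s1,s4	1.0
specificity	tA,H1	1.0
specificity	tB,H1	1.0
specificity	tC,H1	0.5
specificity	tC,H2	0.5
specificity	tD,H2	1.0
specificity	tE,H2	1.0
specificity	tF,H2	1.0
occupancy	tA,H1	1.0
occupancy	tC,H1	0.3333333333333333
occupancy	tC,H2	0.3333333333333333
occupancy	tD,H2	1.0
occupancy	tF,H2	0.6666666666666666
cophenetic	tA,tB	2.0
cophenetic	tC,tD	3.0
cophenetic	tE,tF	2.0
cophenetic	tA,tC	6.0
specialist_set	H1	tA|tB
specialist_set	H2	tD|tE
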