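gene	line_genotype	clone_id	colonies_screened	percent_targeted
Brd8	+/+	.	24	96
Brd8	tm1a/+	E10	22	100
Cbx1	tm1a/+	B01	24	45.8
Ddx27	+/+	.	24	100
Ddx27	tm1a/+	E01	6	0
Dot1l	tm1a/+	D02	24	54.2
Epc2	tm1a/+	B12	24	45.8
Ing3	+/+	.	24	79
Ing3	tm1a/+	E07	16	81
Jarid2	tm1a/+	A08	24	62.5
Jarid2	tm1a/+	E08	24	62.5
Kdm4c	+/+	.	12	100
Kdm4c	tm1a/+	D03	24	75
Mier1	+/+	.	24	66.7
Mier1	tm1a/+	A04	24	66.7
Phf20	+/+	.	24	62.5
Phf20	tm1a/+	F07	0	0
Setdb1	+/+	.	16	100
Setdb1	tm1a/+	D08	40	0
Smyd5	+/+	.	16	62.5
Smyd5	tm1a/+	G01	24	25
Supv3l1	+/+	.	24	50
Supv3l1	tm1a/+	B08	24	70.8
Kmt5b	tm1a/+	C01	24	16.7
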