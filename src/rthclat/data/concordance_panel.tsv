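chemical	gene	ngs_fc	pcr_1	pcr_2	pcr_3	printed_verdict
2,4-Dinitrochlorobenzene	HMOX1	5.2	3.2	3.2	2.9	match
2,4-Dinitrochlorobenzene	JUN	7.7	9.3	10.0	10.0	match
2,4-Dinitrochlorobenzene	PPP1R15A	9.3	8.0	21.1	5.9	match
2,4-Dinitrochlorobenzene	BTG2	3.3	30.7	4.3	2.8	match
2,4-Dinitrochlorobenzene	DDIT3	1.6	1.4	0.7	1.4	match
2,4-Dinitrochlorobenzene	EGR1	5.4	8.3	8.1	8.3	match
2,4-Dinitrochlorobenzene	GADD45B	7.3	8.1	7.4	5.8	match
2,4-Dinitrochlorobenzene	PMAIP1	7.7	6.9	6.5	9.3	match
2,4-Dinitrochlorobenzene	SAT1	2.4	0.5	16.6	1.7	mismatch
2,4-Dinitrochlorobenzene	ULBP2	7.1	1.6	8.5	4.6	match
2,4-Dinitrochlorobenzene	CCR2	0.1	0.2	0.3	0.2	mismatch
2,4-Dinitrochlorobenzene	ICMT	0.5	0.5	0.5	0.7	match
1,4-Phenylendiamine	HMOX1	83.7	66.3	69.6	61.0	match
1,4-Phenylendiamine	JUN	27.2	19.2	22.8	19.2	match
1,4-Phenylendiamine	PPP1R15A	25.6	12.1	19.2	38.9	match
1,4-Phenylendiamine	BTG2	10.1	15.7	16.7	28.8	match
1,4-Phenylendiamine	DDIT3	6.1	5.1	5.5	9.6	match
1,4-Phenylendiamine	EGR1	5.1	14.9	16.4	15.3	mismatch
1,4-Phenylendiamine	GADD45B	14.6	18.3	12.1	25.6	match
1,4-Phenylendiamine	PMAIP1	5.6	4.3	2.9	9.9	match
1,4-Phenylendiamine	SAT1	16.5	8.4	14.4	24.1	match
1,4-Phenylendiamine	ULBP2	8.9	3.7	1.6	12.6	mismatch
1,4-Phenylendiamine	CCR2	0.0	0.1	0.0	0.0	match
1,4-Phenylendiamine	ICMT	0.3	0.3	0.5	0.4	match
Nickel sulfate	HMOX1	3.4	2.3	2.3	2.6	match
Nickel sulfate	JUN	4.5	2.8	3.0	3.1	match
Nickel sulfate	PPP1R15A	3.1	2.2	2.0	4.8	match
Nickel sulfate	BTG2	4.6	3.9	6.8	5.4	match
Nickel sulfate	DDIT3	2.4	1.5	2.2	3.9	match
Nickel sulfate	EGR1	1.1	1.3	1.1	1.0	match
Nickel sulfate	GADD45B	0.9	1.0	0.7	1.4	match
Nickel sulfate	PMAIP1	3.6	2.8	2.6	4.3	match
Nickel sulfate	SAT1	2.3	1.5	2.0	3.5	match
Nickel sulfate	ULBP2	1.4	0.5	0.3	1.8	mismatch
Nickel sulfate	CCR2	0.6	0.6	0.5	0.7	match
Nickel sulfate	ICMT	0.6	0.6	0.8	0.8	match
2-Mercaptobenzothiazole	HMOX1	63.7	39.7	37.3	22.5	match
2-Mercaptobenzothiazole	JUN	25.1	27.6	24.9	25.4	match
2-Mercaptobenzothiazole	PPP1R15A	12.3	10.1	27.3	21.7	match
2-Mercaptobenzothiazole	BTG2	3.8	9.3	6.1	5.2	match
2-Mercaptobenzothiazole	DDIT3	27.2	33.4	11.6	63.1	mismatch
2-Mercaptobenzothiazole	EGR1	3.2	3.9	3.6	3.4	match
2-Mercaptobenzothiazole	GADD45B	6.5	7.9	7.2	8.6	match
2-Mercaptobenzothiazole	PMAIP1	4.5	4.9	3.9	6.5	match
2-Mercaptobenzothiazole	SAT1	12.7	2.2	27.3	27.7	mismatch
2-Mercaptobenzothiazole	ULBP2	4.2	0.9	4.6	8.6	mismatch
2-Mercaptobenzothiazole	CCR2	0.1	0.1	0.1	0.2	match
2-Mercaptobenzothiazole	ICMT	0.4	0.6	0.6	0.6	match
R(+)-Limonene	HMOX1	61.5	62.2	46.9	54.6	match
R(+)-Limonene	JUN	28.1	54.2	54.9	63.6	match
R(+)-Limonene	PPP1R15A	9.1	10.1	29.0	17.8	match
R(+)-Limonene	BTG2	3.5	11.1	4.6	6.1	match
R(+)-Limonene	DDIT3	8.6	9.8	7.4	18.8	match
R(+)-Limonene	EGR1	18.6	50.9	36.5	32.9	match
R(+)-Limonene	GADD45B	3.4	3.5	3.5	3.4	match
R(+)-Limonene	PMAIP1	3.9	3.9	4.2	8.3	match
R(+)-Limonene	SAT1	8.0	3.6	44.6	17.9	mismatch
R(+)-Limonene	ULBP2	7.5	2.2	11.6	17.6	mismatch
R(+)-Limonene	CCR2	0.1	0.5	0.3	0.3	mismatch
R(+)-Limonene	ICMT	0.2	0.5	0.9	0.7	mismatch
Imidazolidinyl urea	HMOX1	7.4	3.9	4.1	4.2	match
Imidazolidinyl urea	JUN	80.0	65.3	46.8	51.9	match
Imidazolidinyl urea	PPP1R15A	15.6	10.9	13.2	17.9	match
Imidazolidinyl urea	BTG2	13.5	15.8	18.6	24.1	match
Imidazolidinyl urea	DDIT3	2.5	2.2	4.6	3.3	match
Imidazolidinyl urea	EGR1	8.3	10.9	8.3	8.6	match
Imidazolidinyl urea	GADD45B	12.0	6.0	5.9	9.3	mismatch
Imidazolidinyl urea	PMAIP1	19.4	14.5	15.8	32.7	match
Imidazolidinyl urea	SAT1	15.0	12.3	18.5	13.1	match
Imidazolidinyl urea	ULBP2	24.3	21.3	11.8	26.7	match
Imidazolidinyl urea	CCR2	0.0	0.0	0.0	0.0	match
Imidazolidinyl urea	ICMT	0.1	0.2	0.2	0.2	mismatch
Isopropanol	HMOX1	1.3	1.6	1.5	1.5	match
Isopropanol	JUN	1.4	0.8	0.7	0.9	match
Isopropanol	PPP1R15A	1.2	1.1	0.9	1.8	match
Isopropanol	BTG2	1.4	1.6	1.5	1.6	match
Isopropanol	DDIT3	1.7	2.3	3.3	3.7	match
Isopropanol	EGR1	0.6	0.8	0.6	0.5	match
Isopropanol	GADD45B	1.2	1.4	0.7	1.9	match
Isopropanol	PMAIP1	1.2	2.1	2.2	2.1	match
Isopropanol	SAT1	1.3	2.1	3.7	2.8	mismatch
Isopropanol	ULBP2	1.1	1.6	0.8	3.0	match
Isopropanol	CCR2	0.8	1.0	0.7	1.2	match
Isopropanol	ICMT	1.0	0.9	1.2	1.1	match
Glycerol	HMOX1	1.5	1.4	1.6	0.9	match
Glycerol	JUN	1.2	0.8	1.2	0.8	match
Glycerol	PPP1R15A	1.0	1.0	1.0	1.1	match
Glycerol	BTG2	0.9	1.4	1.3	0.8	match
Glycerol	DDIT3	1.1	1.1	1.2	1.6	match
Glycerol	EGR1	1.1	1.6	1.0	1.0	match
Glycerol	GADD45B	0.9	1.1	0.7	1.1	match
Glycerol	PMAIP1	1.1	1.3	1.0	2.0	match
Glycerol	SAT1	1.0	1.0	1.5	1.9	match
Glycerol	ULBP2	0.8	0.9	0.4	2.1	match
Glycerol	CCR2	1.2	1.8	1.1	1.1	match
Glycerol	ICMT	0.9	0.7	1.5	1.1	match
4-Aminobenzoic acid	HMOX1	1.3	0.8	0.8	0.9	match
4-Aminobenzoic acid	JUN	0.6	0.8	0.6	0.8	match
4-Aminobenzoic acid	PPP1R15A	1.0	0.8	2.0	0.9	match
4-Aminobenzoic acid	BTG2	1.4	1.7	1.1	4.5	match
4-Aminobenzoic acid	DDIT3	0.9	0.8	0.3	1.2	match
4-Aminobenzoic acid	EGR1	0.5	0.8	0.5	0.6	match
4-Aminobenzoic acid	GADD45B	1.1	1.0	0.7	0.6	match
4-Aminobenzoic acid	PMAIP1	1.3	0.9	0.8	8.2	match
4-Aminobenzoic acid	SAT1	1.1	0.3	3.8	1.8	match
4-Aminobenzoic acid	ULBP2	1.6	0.4	1.2	2.1	match
4-Aminobenzoic acid	CCR2	0.7	0.6	0.8	0.5	match
4-Aminobenzoic acid	ICMT	0.9	3.3	0.9	1.0	match
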