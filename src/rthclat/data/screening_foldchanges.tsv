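chemical	gene	replicate	fold_change
Potassium dichromate	HMOX1	1	0.9
Potassium dichromate	HMOX1	2	0.6
Potassium dichromate	HMOX1	3	0.4
Potassium dichromate	JUN	1	1.3
Potassium dichromate	JUN	2	1.0
Potassium dichromate	JUN	3	1.0
Benzoyl peroxide	HMOX1	1	1.9
Benzoyl peroxide	HMOX1	2	1.4
Benzoyl peroxide	HMOX1	3	1.5
Benzoyl peroxide	JUN	1	3.0
Benzoyl peroxide	JUN	2	2.2
Benzoyl peroxide	JUN	3	2.0
Cobalt chloride	HMOX1	1	11.4
Cobalt chloride	HMOX1	2	18.0
Cobalt chloride	HMOX1	3	18.8
Cobalt chloride	JUN	1	1.4
Cobalt chloride	JUN	2	1.4
Cobalt chloride	JUN	3	1.2
4-Nitrobenzyl bromide	HMOX1	1	92.8
4-Nitrobenzyl bromide	HMOX1	2	175.7
4-Nitrobenzyl bromide	HMOX1	3	135.9
4-Nitrobenzyl bromide	JUN	1	11.8
4-Nitrobenzyl bromide	JUN	2	21.6
4-Nitrobenzyl bromide	JUN	3	22.4
Maleic acid	HMOX1	1	10.7
Maleic acid	HMOX1	2	11.6
Maleic acid	HMOX1	3	13.2
Maleic acid	JUN	1	1.3
Maleic acid	JUN	2	2.0
Maleic acid	JUN	3	1.3
2-Aminophenol	HMOX1	1	2.5
2-Aminophenol	HMOX1	2	4.2
2-Aminophenol	HMOX1	3	3.2
2-Aminophenol	JUN	1	6.7
2-Aminophenol	JUN	2	8.5
2-Aminophenol	JUN	3	8.0
Lauryl gallate	HMOX1	1	1.7
Lauryl gallate	HMOX1	2	1.4
Lauryl gallate	HMOX1	3	1.3
Lauryl gallate	JUN	1	5.8
Lauryl gallate	JUN	2	7.0
Lauryl gallate	JUN	3	6.6
Methyl methanesulfonate	HMOX1	1	3.3
Methyl methanesulfonate	HMOX1	2	2.3
Methyl methanesulfonate	HMOX1	3	3.6
Methyl methanesulfonate	JUN	1	1.6
Methyl methanesulfonate	JUN	2	1.3
Methyl methanesulfonate	JUN	3	1.6
Citral	HMOX1	1	220.8
Citral	HMOX1	2	176.9
Citral	HMOX1	3	211.8
Citral	JUN	1	5.9
Citral	JUN	2	4.9
Citral	JUN	3	6.9
Resorcinol	HMOX1	1	1.1
Resorcinol	HMOX1	2	1.2
Resorcinol	HMOX1	3	1.7
Resorcinol	JUN	1	13.6
Resorcinol	JUN	2	13.2
Resorcinol	JUN	3	14.4
Diethylenetriamine	HMOX1	1	19.9
Diethylenetriamine	HMOX1	2	22.3
Diethylenetriamine	HMOX1	3	19.9
Diethylenetriamine	JUN	1	1.8
Diethylenetriamine	JUN	2	2.1
Diethylenetriamine	JUN	3	1.9
Cinnamaldehyde	HMOX1	1	0.7
Cinnamaldehyde	HMOX1	2	0.4
Cinnamaldehyde	HMOX1	3	0.5
Cinnamaldehyde	JUN	1	4.4
Cinnamaldehyde	JUN	2	3.2
Cinnamaldehyde	JUN	3	3.0
3-Propylidenephthalide	HMOX1	1	135.0
3-Propylidenephthalide	HMOX1	2	27.0
3-Propylidenephthalide	HMOX1	3	11.0
3-Propylidenephthalide	JUN	1	2.4
3-Propylidenephthalide	JUN	2	2.0
3-Propylidenephthalide	JUN	3	2.9
Phenylacetaldehyde	HMOX1	1	16.1
Phenylacetaldehyde	HMOX1	2	18.2
Phenylacetaldehyde	HMOX1	3	29.7
Phenylacetaldehyde	JUN	1	3.5
Phenylacetaldehyde	JUN	2	11.7
Phenylacetaldehyde	JUN	3	11.0
3-Dimethylamino propylamine	HMOX1	1	79.5
3-Dimethylamino propylamine	HMOX1	2	46.6
3-Dimethylamino propylamine	HMOX1	3	69.7
3-Dimethylamino propylamine	JUN	1	4.9
3-Dimethylamino propylamine	JUN	2	2.7
3-Dimethylamino propylamine	JUN	3	2.6
1-Phenyl-1,2-propanedione	HMOX1	1	18.2
1-Phenyl-1,2-propanedione	HMOX1	2	17.0
1-Phenyl-1,2-propanedione	HMOX1	3	19.7
1-Phenyl-1,2-propanedione	JUN	1	7.8
1-Phenyl-1,2-propanedione	JUN	2	7.3
1-Phenyl-1,2-propanedione	JUN	3	6.8
Isoeugenol	HMOX1	1	14.7
Isoeugenol	HMOX1	2	13.3
Isoeugenol	HMOX1	3	19.3
Isoeugenol	JUN	1	3.4
Isoeugenol	JUN	2	4.3
Isoeugenol	JUN	3	6.3
Oxalic acid anhydrous	HMOX1	1	4.6
Oxalic acid anhydrous	HMOX1	2	3.2
Oxalic acid anhydrous	HMOX1	3	3.4
Oxalic acid anhydrous	JUN	1	0.6
Oxalic acid anhydrous	JUN	2	0.5
Oxalic acid anhydrous	JUN	3	0.5
Geraniol	HMOX1	1	6.7
Geraniol	HMOX1	2	8.9
Geraniol	HMOX1	3	7.7
Geraniol	JUN	1	13.0
Geraniol	JUN	2	15.2
Geraniol	JUN	3	10.3
1,2-Propanediol	HMOX1	1	0.4
1,2-Propanediol	HMOX1	2	0.4
1,2-Propanediol	HMOX1	3	0.7
1,2-Propanediol	JUN	1	0.6
1,2-Propanediol	JUN	2	0.6
1,2-Propanediol	JUN	3	0.7
4-Hydroxybenzoic acid	HMOX1	1	0.6
4-Hydroxybenzoic acid	HMOX1	2	0.7
4-Hydroxybenzoic acid	HMOX1	3	0.8
4-Hydroxybenzoic acid	JUN	1	1.0
4-Hydroxybenzoic acid	JUN	2	1.1
4-Hydroxybenzoic acid	JUN	3	0.8
Sulfanilamide	HMOX1	1	0.8
Sulfanilamide	HMOX1	2	0.7
Sulfanilamide	HMOX1	3	0.9
Sulfanilamide	JUN	1	0.7
Sulfanilamide	JUN	2	0.5
Sulfanilamide	JUN	3	0.8
Coumarin	HMOX1	1	0.8
Coumarin	HMOX1	2	0.9
Coumarin	HMOX1	3	1.0
Coumarin	JUN	1	8.3
Coumarin	JUN	2	7.8
Coumarin	JUN	3	6.3
4-Methoxyacetophenone	HMOX1	1	0.4
4-Methoxyacetophenone	HMOX1	2	0.4
4-Methoxyacetophenone	HMOX1	3	0.2
4-Methoxyacetophenone	JUN	1	1.3
4-Methoxyacetophenone	JUN	2	1.9
4-Methoxyacetophenone	JUN	3	1.2
Ethyl benzoylacetate	HMOX1	1	0.9
Ethyl benzoylacetate	HMOX1	2	1.3
Ethyl benzoylacetate	HMOX1	3	2.0
Ethyl benzoylacetate	JUN	1	2.5
Ethyl benzoylacetate	JUN	2	3.9
Ethyl benzoylacetate	JUN	3	11.2
1-Butanol	HMOX1	1	0.7
1-Butanol	HMOX1	2	0.7
1-Butanol	HMOX1	3	0.9
1-Butanol	JUN	1	1.0
1-Butanol	JUN	2	0.9
1-Butanol	JUN	3	1.4
Saccharin	HMOX1	1	2.0
Saccharin	HMOX1	2	1.1
Saccharin	HMOX1	3	2.2
Saccharin	JUN	1	0.6
Saccharin	JUN	2	0.4
Saccharin	JUN	3	0.8
Sodium Sulfite	HMOX1	1	0.5
Sodium Sulfite	HMOX1	2	0.4
Sodium Sulfite	HMOX1	3	0.4
Sodium Sulfite	JUN	1	3.5
Sodium Sulfite	JUN	2	3.9
Sodium Sulfite	JUN	3	6.5
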