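name	abbreviation	cas	solvent	cv75	llna_category	hclat_judgment	panel
2,4-Dinitrochlorobenzene	DNCB	97-00-7	DMSO		extreme	p	reference
1,4-Phenylendiamine	PPDA				strong	p	reference
Nickel sulfate	NiSO4				moderate	p	reference
2-Mercaptobenzothiazole	MBT				moderate	p	reference
R(+)-Limonene	LIM				weak	p	reference
Imidazolidinyl urea	IU				weak	p	reference
Isopropanol					non_sensitizer	n	reference
Glycerol					non_sensitizer	n	reference
4-Aminobenzoic acid					non_sensitizer	n	reference
Potassium dichromate					extreme	p	screening
Benzoyl peroxide					extreme	n	screening
Cobalt chloride					strong	p	screening
4-Nitrobenzyl bromide					strong	p	screening
Maleic acid					strong	p	screening
2-Aminophenol					strong	p	screening
Lauryl gallate					strong	p	screening
Methyl methanesulfonate					moderate	n	screening
Citral					moderate	p	screening
Resorcinol					moderate	p	screening
Diethylenetriamine					moderate	n	screening
Cinnamaldehyde					moderate	p	screening
3-Propylidenephthalide					moderate	p	screening
Phenylacetaldehyde					moderate	p	screening
3-Dimethylamino propylamine					moderate	p	screening
1-Phenyl-1,2-propanedione					moderate	p	screening
Isoeugenol					moderate	n	screening
Oxalic acid anhydrous					weak	p	screening
Geraniol					weak	p	screening
1,2-Propanediol					non_sensitizer	n	screening
4-Hydroxybenzoic acid					non_sensitizer	n	screening
Sulfanilamide					non_sensitizer	n	screening
Coumarin					non_sensitizer	n	screening
4-Methoxyacetophenone					non_sensitizer	n	screening
Ethyl benzoylacetate					non_sensitizer	n	screening
1-Butanol					non_sensitizer	n	screening
Saccharin					non_sensitizer	n	screening
Sodium Sulfite					ND	p	screening
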