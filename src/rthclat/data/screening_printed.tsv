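chemical	printed_call	printed_match
Potassium dichromate	non_sensitizer	mismatch
Benzoyl peroxide	sensitizer	match
Cobalt chloride	sensitizer	match
4-Nitrobenzyl bromide	sensitizer	match
Maleic acid	sensitizer	match
2-Aminophenol	sensitizer	match
Lauryl gallate	sensitizer	match
Methyl methanesulfonate	sensitizer	match
Citral	sensitizer	match
Resorcinol	sensitizer	match
Diethylenetriamine	sensitizer	match
Cinnamaldehyde	sensitizer	match
3-Propylidenephthalide	sensitizer	match
Phenylacetaldehyde	sensitizer	match
3-Dimethylamino propylamine	sensitizer	match
1-Phenyl-1,2-propanedione	sensitizer	match
Isoeugenol	sensitizer	match
Oxalic acid anhydrous	sensitizer	match
Geraniol	sensitizer	match
1,2-Propanediol	non_sensitizer	match
4-Hydroxybenzoic acid	non_sensitizer	match
Sulfanilamide	non_sensitizer	match
Coumarin	sensitizer	mismatch
4-Methoxyacetophenone	non_sensitizer	match
Ethyl benzoylacetate	sensitizer	mismatch
1-Butanol	non_sensitizer	match
Saccharin	sensitizer	mismatch
Sodium Sulfite	sensitizer	not_evaluable
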