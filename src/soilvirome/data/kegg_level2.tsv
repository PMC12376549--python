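ko_id	kegg_level2
K00239	Carbohydrate metabolism
K00615	Carbohydrate metabolism
K00845	Carbohydrate metabolism
K00850	Carbohydrate metabolism
K00963	Carbohydrate metabolism
K01176	Carbohydrate metabolism
K01179	Carbohydrate metabolism
K01187	Carbohydrate metabolism
K01188	Carbohydrate metabolism
K01810	Carbohydrate metabolism
K00018	Energy metabolism
K00024	Energy metabolism
K00192	Energy metabolism
K00370	Energy metabolism
K01601	Energy metabolism
K01602	Energy metabolism
K01595	Energy metabolism
K01648	Energy metabolism
K02703	Energy metabolism
K00030	Amino acid metabolism
K00058	Amino acid metabolism
K00265	Amino acid metabolism
K01915	Amino acid metabolism
K00525	Nucleotide metabolism
K00560	Nucleotide metabolism
K00788	Metabolism of cofactors and vitamins
K00794	Metabolism of cofactors and vitamins
K03639	Metabolism of cofactors and vitamins
K00640	Energy metabolism
K00860	Energy metabolism
K00957	Energy metabolism
K00626	Lipid metabolism
K00059	Lipid metabolism
K00648	Lipid metabolism
K13811	Energy metabolism
K02706	Energy metabolism
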