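name	synonyms	chebi_id	is_curated_matrix	is_matrix
α-cyano-4-hydroxycinnamic acid	CHCA;HCCA;4-HCCA;alpha-cyano-4-hydroxycinnamic acid	CHEBI:77936	1	1
2,5-dihydroxybenzoic acid	DHB;gentisic acid	CHEBI:27693	1	1
trans-sinapic acid	sinapic acid;sinapinic acid	CHEBI:27823	1	1
3-hydroxypicolinic acid	3-HPA;3-hydroxypyridine-2-carboxylic acid		1	1
9-aminoacridine	9-AA;aminacrine	CHEBI:2619	1	1
2′,4′,6′-trihydroxyacetophenone	THAP;2,4,6-trihydroxyacetophenone		1	1
1,5-diaminonaphthalene	1,5-DAN;naphthalene-1,5-diamine		0	1
trans-2-[3-(4-tert-butylphenyl)-2-methyl-2-propenylidene]malononitrile	DCTB		1	1
2,5-dihydroxyacetophenone	DHAP		0	1
1,3-benzothiazole-2-thiol	2-mercaptobenzothiazole;MBT		0	1
4-chloro-α-cyanocinnamic acid	ClCCA;CClCA;4-chloro-alpha-cyanocinnamic acid		0	1
2-(4-hydroxyphenylazo)benzoic acid	HABA		1	1
terthiophene	2,2':5',2''-terthiophene;alpha-terthiophene		0	1
1,8-bis(dimethylamino)naphthalene	DMAN;proton sponge		0	1
9,10-diphenylanthracene			0	1
2,4-diphenyl-pyranylium	2,4-diphenylpyrylium		0	1
poly(phenylenevinylene)	polyphenylenevinylene;PPV polymer		0	1
meso-tetrakis(pentafluorophenyl)porphyrin	TPFPP		0	1
4-phenyl-α-cyanocinnamic acid amide	PhCCAA;4-phenyl-alpha-cyanocinnamic acid amide		0	1
adenosine		CHEBI:16335	0	0
alanine		CHEBI:16449	0	0
ascorbic acid	vitamin C	CHEBI:29073	0	0
chlorophyll		CHEBI:28966	0	0
cholesterol		CHEBI:16113	0	0
cisplatin		CHEBI:27899	0	0
cocaine		CHEBI:27958	0	0
glucose		CHEBI:17234	0	0
nicotine		CHEBI:18723	0	0
water		CHEBI:15377	0	0
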