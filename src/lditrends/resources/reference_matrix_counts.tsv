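name	with_maldi	total	sm_pp	sm_op	curated
α-cyano-4-hydroxycinnamic acid	9178	11431	0.16	0.53	1
2,5-dihydroxybenzoic acid	4293	7687	0.24	0.51	1
trans-sinapic acid	517	4688	0.24	0.51	1
3-hydroxypicolinic acid	505	626	0.20	0.40	1
9-aminoacridine	459	2183	0.38	1.05	1
2′,4′,6′-trihydroxyacetophenone	421	641	0.25	0.49	1
1,5-diaminonaphthalene	241	452	0.33	1.24	0
trans-2-[3-(4-tert-butylphenyl)-2-methyl-2-propenylidene]malononitrile	195	199	0.35	0.22	1
2,5-dihydroxyacetophenone	181	267	0.26	0.62	0
1,3-benzothiazole-2-thiol	152	952	0.27	0.80	0
4-chloro-α-cyanocinnamic acid	80	83	0.27	1.11	0
2-(4-hydroxyphenylazo)benzoic acid	75	137	0.39	0.43	1
terthiophene	62	837	0.82	0.38	0
1,8-bis(dimethylamino)naphthalene	42	233	0.54	0.94	0
9,10-diphenylanthracene	34	524	0.36	0.31	0
2,4-diphenyl-pyranylium	20	24	0.58	1.22	0
poly(phenylenevinylene)	19	314	1.00	0.32	0
meso-tetrakis(pentafluorophenyl)porphyrin	18	69	0.91	1.11	0
4-phenyl-α-cyanocinnamic acid amide	13	13	0.58	0.88	0
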