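mirna	unique_condition	target_id	gene_name	function	t_start	t_stop	cleavage_site	category	allen_score	p_value	mfe_perfect	mfe_site	sequence	structure
miR5493		Os06t0592500-01		Heat stress response	239	259	249	4	9	0.999999999998832	-48.2	-32	CGGGGGCGGCGGCGCCCGCGCG&AGC-CGGGCUCUGUCGCGCGUG	((.(.(((((((.(((((.((.&.))-))))).))))))).).))
miR5493		Os01t0226600-01	OsSLAC	panicle size and grain yield	646	668	657	4	10	0.99492685305248	-48.2	-34.6	CGCGCGCGGCGGCGGCGGCGGCG&AGCCG-GGCU-CUGUCGCGCGUG	((((((((((((.(((..((((.&.))))-.)))-))))))))))))
miR5493		Os02t0202400-01	OsBT1-1	grain formation by controlling starch synthesis	1026	1048	1038	2	9.5	0.957334082969076	-48.2	-33.4	GGCGCGCCGACGUCGGCCCGGCC&AGCCGGGCU-CUGUCG-CGCGUG	.(((((.(((((..((((((((.&.))))))))-.)))))-))))).
miR160b-3p	shade	Os04t0104900-01	OsCOMTL2	methyltransferase	218	240	230	4	7.5	0.69392523364486	-42.8	-29.7	CAUGCUGAGGCUCCUCGCGUCGU&GCG-UGCAAGGAGCC-AAGCAUG	((((((..(((((((.(((.(((&)))-))).)))))))-.))))))
miR169-p	sun	Os01t0188400-01	OschlME	NADP-dependent malic enzyme	1621	1645	1635	4	13.5	0.906795694004373	-39.1	-27.7	GAGCCAGGGUCGUGCAGUAUUUGCC&GGCAAGU-CUGU----CCUUGGCUA	.((((((((....((((.(((((((&)))))))-))))----)))))))).
miR399b		Os03t0761100-02	OsPP2C	stress tolerance. ABA-signalling	217	236	228	4	9	0.779612379437849	-39.6	-26	CGGGGGAGUUCUCGA-UGGCG&UGCCAAAGGAGAAUUGCCCUG	(((((.(((((((..-((((.&.))))...))))))).)))))
miR1439		Os01t0281000-01	OsFbox6 OsFBX5 OsSTA12	cyclin F-box containing protein	2027	2049	2038	4	9	0.969782287321394	-31.6	-20.7	AUUGCUCAUUCUGUAUUCUGAAA&UUUUGGA--ACAGAGUGAGUAUU	..((((((((((((..(((((((&)))))))--))))))))))))..
miR414		Os06t0561200-01		Potassium/proton antiporter	132	151	142	4	4.5	0.997646941389551	-36.4	-26.8	UCCUCCUCGUCCUCGUCGUU&GACGAUGAUGACGAGGAUGA	((.((((((((.((((((((&)))))))).)))))))).))
miR414		Os10t0503800-01	OsREM1.2	Membrane protein, plant growth, development, stress responses	734	753	744	4	3.5	0.809937142647283	-36.4	-30.7	UCGUCGUCGUCGUCGUCGUU&GACGAUGAUGACGAGGAUGA	(((((.((((((((((((((&)))))))))))))).)))))
miR6245		Os07t0551600-01	OsCslF9	mechanical Strength of stem	1716	1732	1723	4	11	0.97682345	-19.6	-10.2	AGGCCGGCGCC&GGUGUCGGCACU	(((((((((((&))))))))).))
miR5075		Os02t0285300-01	OsDREPP2	plasma membrane protein	361	371	369	4	5	1	-40.2	-27.5	CUCCGCCGCCGUCA-CCA&CGGAUGGCGGCGACGGAG	(((((.((((((((-((.&.)).)))))))).)))))
miR529a		Os03t0787300-01	OsDjA5	co-chaperones	1235	1255	1246	4	9	0.999999999991589	-36.7	-24.6	GAGGAGGAGAUGAGGAGGCGG&CUGUACCCUC-UCUCUUCUUC	((((((((((.((((..((((&))))..))))-))))))))))
miR444.2		Os05t0549800-01	OsEREBP96	transcription factor in ethylene signalling	564	584	575	1	8	0.443890721132931	-40.1	-26.7	CCGCCGGCGGCGGCGAUUGCA&UGCAGUUGCUGCCUCAAGCUU	..((..(.(((((((((((((&))))))))))))).)..))..
miR5810		Os10t0392400-01	OsTIFY11D	jasmonate signalling	692	704	699	4	13	0.999999999324921	-28.98	-6.48	AUUGUUGUUUUCC&GGAACCCUAACAGCGAU	(((((((((((((&))))....)))))))))
miR2275b		Os05t0402700-01	OsFBA	formation of SBP and FBP, increase photosynthetic carbon flux, RUBP regeneration, promote gibberellin mediated root growth	337	350	341	2	5	0.440673027304968	-34	-22.18	CCUCCAGUACCUCA&UGAGAUACUGGAGG	((...(((((((((.((((&)))).)))))))))...))
miR5487		Os02t0771700-01	OsGns9	glycoside hydrolase pollen development, seed germination, cold response	862	884	878	4	20	0.652419432123166	-34.6	-24.6	GGAACUACAAUGCCGUGCGCGUCGUG&GAUGUGCAUGUAGUUCC	(((((((((......((((((((&)))))))))))))))))
miR5144-5p		Os01t0725800-01	OsWD40-24	repressors of photomorphogeneis, stomatal closure, mesophyll photosynthesis, sucrose breakdown	435	455	446	4	9	0.713872072328414	-37.9	-25.8	GUCUCGGCAGCAGCGGGUGGA&UUCUUGUGCUGCUGAAGAGAC	(((((..((((((((.(.(((&))).).))))))))..)))))
miR5144-5p		Os01t0588900-01	OsLOG1	Cytokinin-activating enzyme	474	492	483	4	6	0.854853045446532	-37.9	-25.8	GUCUCUGGCAUGCACGAGA&UUCUUGUGCUGCUGAAGAGAC	((((((.(((.((((((((&)))))))))))...))))))
miR172b		Os03t0171700-01	OsbHLH153	flag leaf angle	303	321	313	4	6.5	0.926716620410872	-36	-24.6	UGCAGCUACAUCAAGAGCC&GGAAUCUUGAUGAUGCUGCA	((((((..((((((((.((&))..))))))))..))))))
miR168b		Os11t0255300-01	OsCP1	cysteine protease pollen development	1036	1052	1044	4	6	0.999999999999982	-30	-20.3	ACUCGAGACGGCACCAAG&CUUGGUGCAGCUCGGG	((((((...((((((((&))))))))..))))))
miR168b		Os01t0104600-01	OsDET1	repressors of photomorphogeneis	358	375	366	4	6	0.999999999973558	-38.4	-25.9	GCCCGCGCCGCAGCAAGC&GCUUGGUGCAGCUCGGGA	.((((.((.(((.(((((&))))).))).)).))))
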