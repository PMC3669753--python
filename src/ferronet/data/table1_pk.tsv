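gene_id	function	mean_ratio	sd_ratio	subfamily
AT2G19410	Protein kinase family protein	10.26	0.95	RLCK
AT5G53450	ORG1 (OBP3-responsive gene 1); ATP binding/kinase/protein kinase	5.24	0.18
AT5G01060	Protein kinase family protein	5.01	0.85	RLCK
AT1G51870	Protein kinase family protein	4.10	2.00	RLK
AT1G77280	Protein kinase family protein	4.09	0.46	RLCK
AT4G38830	Protein kinase family protein	3.54	0.49	RLK
AT1G16120	WAKL1 (wall associated kinase-like 1)	2.76	0.57	RLK
AT5G39000	protein kinase family protein	2.75	0.63	RLK
AT1G16150	WAKL4 (WALL ASSOCIATED KINASE-LIKE 4)	2.72	0.39	RLK
AT5G23170	Protein kinase family protein	2.62	0.40	RLCK
AT1G05700	Leucine-rich repeat protein kinase	2.60	0.40	RLK
AT1G51830	ATP binding/kinase/protein serine/threonine kinase	2.58	0.19	RLK
AT4G26890	MAPKKK16; ATP binding/kinase/protein kinase/protein serine/threonine kinase/protein tyrosine kinase	2.18	0.13	Group-C
AT5G07280	EMS1 (EXCESS MICROSPOROCYTES1); kinase/transmembrane receptor protein kinase	2.14	0.27	RLK
AT1G33260	Protein kinase family protein	2.03	0.19	RLCK
AT1G51860	Leucine-rich repeat protein kinase	2.02	0.32	RLK
AT1G72540	Protein kinase, putative	1.97	0.33	RLCK
AT2G28990	Leucine-rich repeat protein kinase	1.96	0.08	RLK
AT5G60280	Lectin protein kinase family protein	1.93	0.36	RLK
AT4G18700	CIPK12 (CBL-INTERACTING PROTEIN KINASE 12); ATP binding/kinase/protein kinase/protein serine/threonine kinase	1.91	0.12	CAMK_AMPK
AT2G45590	Protein kinase family protein	1.89	0.32	RLCK
AT2G30360	SIP4 (SOS3-INTERACTING PROTEIN 4); kinase/protein kinase	1.89	0.21	CAMK_CDPK
AT3G46330	MEE39 (maternal effect embryo arrest 39)	1.78	0.28	RLK
AT1G51620	Protein kinase family protein	1.78	0.55	RLCK
AT1G08650	PPCK1 (PHOSPHOENOLPYRUVATE CARBOXYLASE KINASE); kinase/protein serine/threonine kinase	1.78	0.16	CAMK_CDPK
AT5G35580	ATP binding/kinase/protein kinase/protein serine/threonine kinase/protein tyrosine kinase	1.73	0.44	RLCK
AT3G49370	CDPK-related kinase	1.71	0.30	CAMK_AMPK
AT1G01140	CIPK9 (CBL-INTERACTING PROTEIN KINASE 9); ATP binding/kinase/protein kinase/protein serine/threonine kinase	1.71	0.37	CAMK_CDPK
AT3G27580	ATPK7; kinase/protein serine/threonine kinase	1.69	0.21	AGC_S6K
AT1G16160	WAKL5 (wall associated kinase-like 5)	1.64	0.34	RLK
AT3G45330	Lectin protein kinase family protein	1.62	0.19	RLK
AT5G55560	Protein kinase family protein	1.62	0.34	Other_WNK
AT1G07560	Leucine-rich repeat protein kinase	1.61	0.21	RLK
AT3G57740	Protein kinase family protein	1.61	0.39	RLCK
AT5G25440	Protein kinase family protein	1.59	0.16	RLCK
AT1G51800	Leucine-rich repeat protein kinase	1.58	0.12	RLK
AT1G66930	Serine/threonine protein kinase family protein	1.57	0.15	RLK
AT1G74360	Leucine-rich repeat transmembrane protein kinase	1.56	0.22	RLK
AT5G16900	Leucine-rich repeat protein kinase	1.56	0.15	RLK
AT4G04700	CPK27; ATP binding/calcium ion binding/kinase/protein kinase/protein serine/threonine kinase/protein tyrosine kinase	1.56	0.16	CAMK_CDPK
AT5G35750	AHK2 (ARABIDOPSIS HISTIDINE KINASE 2); cytokinin receptor/osmosensor/protein histidine kinase	1.56	0.03
AT2G46700	CDPK-related kinase	1.52	0.11	CAMK_AMPK
AT3G50230	Leucine-rich repeat transmembrane protein kinase	0.64	0.09	RLK
AT5G49760	Leucine-rich repeat family protein/protein kinase family protein	0.63	0.04	RLK
AT1G61480	S-locus protein kinase, putative	0.62	0.04	RLK
AT5G49780	ATP binding/kinase/protein serine/threonine kinase	0.62	0.03	RLK
AT2G25090	CIPK16 (CBL-INTERACTING PROTEIN KINASE 16); ATP binding/kinase/protein kinase/protein serine/threonine kinase	0.61	0.09	CAMK_AMPK
AT5G59660	Leucine-rich repeat protein kinase	0.60	0.05	RLK
AT1G07150	MAPKKK13; ATP binding/kinase/protein kinase/protein serine/threonine kinase	0.60	0.13	Group-C
AT2G18470	Protein kinase family protein	0.53	0.11	RLK
AT1G74490	Protein kinase, putative	0.46	0.09	RLCK
AT1G21230	WAK5 (WALL ASSOCIATED KINASE 5)	0.44	0.14	RLK
AT4G40010	SNRK2.7 (SNF1-RELATED PROTEIN KINASE 2.7)	0.44	0.08	Group-A
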