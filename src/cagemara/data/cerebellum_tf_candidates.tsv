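refseq	symbol	mean	max	ko_phenotype	evidence	is_known_cerebellar
NM_010496	Id2	34	1529	postnatal lethality	Y	0
NM_057172	Fubp1	252	469	NO KO		0
NM_011865	Pcbp1	212	365	NO KO	Y	0
NM_016889	Insm1	74	183	perinatal and neonatal lethality	Y	0
NM_001160410	Scrt2	80	180	NO KO	Y	0
NM_001008542	Mxi1	90	168	progressive hyperplasia in the spleen and prostate	Y	0
NM_009716	Atf4	117	167	postnatal lethality	Y	0
NM_130893	Scrt1	76	161	NO KO		0
NM_001103165	Pcbp2	90	147	NO KO		0
NM_001024918	Rfx4	52	138	missing dorsal-mid line structure of the cortex, neonatal lethality	Y	0
NM_009628	Adnp	100	132	embryonic death between E8.5 and E9		0
NM_010772	Maz	101	128	NO KO	Y	0
NM_011265	Rfx3	77	127	embryonic and perinatal lethality	Y	0
NM_181322	Ctcf	86	120	die prior to E9.5		0
NM_013780	Npas3	56	114	exhibit abnormal behavior and nervous system morphology	Y	0
NM_001085492	Rere	65	88	embryonic lethality with abnormalities in neural tube development		0
NM_011732	Ybx1	60	86	embryonic and perinatal lethality		0
NM_001093776	Myt1l	49	85	NO KO	Y	0
NM_023739	Nfx1	74	84	NO KO		0
NM_015753	Zeb2	41	83	embryonic death between embryonic days 9.5 and 10.5	Y	0
NM_010894	Neurod1	299	1035	known cerebellar regulator		1
NM_009573	Zic1	216	408	known cerebellar regulator		1
NM_001244200	Pax6	58	107	known cerebellar regulator		1
NM_001289916	Rora	35	59	known cerebellar regulator		1
NM_007500	Atoh1	28	58	known cerebellar regulator		1
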