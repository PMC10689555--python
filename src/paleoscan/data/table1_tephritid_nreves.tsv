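name	species	accession	start	length	region	transcript_detection
nrEVE_BcucNarna_1	B. cucurbitae	NW_011863697.1	79633	221	RdRp	0/4
nrEVE_BdorPartiti_1	B. dorsalis	NW_011869496.1	975	215	Capsid	3/4
nrEVE_BdorRhabdo_2	B. dorsalis	NW_011874984.1	8863	1175	Capsid	3/4
nrEVE_BdorRhabdo_1	B. dorsalis	NW_011876088.1	19970	2719	Capsid	3/4
nrEVE_BlatToti_1	B. latifrons	NW_017534628.1	40607	134	RdRp	0/4
nrEVE_BlatVirga_1	B. latifrons	NW_017534907.1	8651	149	Hypothetical	1/4
nrEVE_BlatPartiti_1	B. latifrons	NW_017536152.1	2791	233	Hypothetical	0/4
nrEVE_BlatRhabdo_1	B. latifrons	NW_017537113.1	49913	485	RdRp	4/4
nrEVE_BoleUnc_1	B. oleae	LGAM02010267.1	1012	281	Hypothetical	0/4
nrEVE_BolePartiti_1	B. oleae	LGAM02013578.1	63099	1376	Capsid	0/4
nrEVE_BoleTymo_1	B. oleae	LGAM02022319.1	8889	419	Capsid	0/4
nrEVE_BoleVirga_1	B. oleae	LGAM02022319.1	9879	173	Hypothetical	0/4
nrEVE_BoleRhabdo_1	B. oleae	LGAM02022611.1	270159	107	Capsid	4/4
nrEVE_BolePhasma_3	B. oleae	LGAM02022787.1	16056	773	Glycoprotein	0/4
nrEVE_BolePhasma_2	B. oleae	LGAM02022787.1	20198	862	Glycoprotein	0/4
nrEVE_BolePhasma_1	B. oleae	LGAM02022787.1	24720	1228	Glycoprotein	0/4
nrEVE_BtryUnc_2	B. tryoni	JHQJ01000026.1	12845	1125	Hypothetical	0/4
nrEVE_BtryRhabdo_1	B. tryoni	JHQJ01000078.1	417965	1373	Capsid	1/4
nrEVE_BtryPartiti_3	B. tryoni	JHQJ01001339.1	64465	473	Capsid	0/4
nrEVE_BtryUnc_1	B. tryoni	JHQJ01002975.1	7854	449	Hypothetical	0/4
nrEVE_BtryRhabdo_2	B. tryoni	JHQJ01003828.1	34340	701	Glycoprotein	0/4
nrEVE_BtryPartiti_1	B. tryoni	JHQJ01008948.1	8943	542	Capsid	0/4
nrEVE_BtryToti_1	B. tryoni	JHQJ01010486.1	2654	254	Hypothetical	0/4
nrEVE_BtryPartiti_2	B. tryoni	JHQJ01022891.1	142	494	Capsid	0/4
nrEVE_CcapPhenui_1	C. capitata	NW_019376369.1	394469	290	Capsid	3/4
nrEVE_CcapRhabdo_1	C. capitata	NW_019378575.1	201736	629	Glycoprotein	4/4
nrEVE_CcapRhabdo_2	C. capitata	NW_019378578.1	708556	276	RdRp	0/4
nrEVE_CcapPartiti_1	C. capitata	NW_019378583.1	1219447	320	Capsid	4/4
nrEVE_EdiaRhabdo_7	E. diana	JXPB01001061.1	1811	769	Capsid	-
nrEVE_EdiaTombus_2	E. diana	JXPB01011939.1	2277	851	RdRp	-
nrEVE_EdiaRhabdo_6	E. diana	JXPB01023432.1	2431	680	Capsid	-
nrEVE_EdiaRhabdo_2	E. diana	JXPB01041133.1	515	266	Capsid	-
nrEVE_EdiaRhabdo_5	E. diana	JXPB01041133.1	867	590	Capsid	-
nrEVE_EdiaRhabdo_4	E. diana	JXPB01048060.1	1429	347	Hypothetical	-
nrEVE_EdiaPhenui_3	E. diana	JXPB01052776.1	249	751	Capsid	-
nrEVE_EdiaOrthomyxo_2	E. diana	JXPB01059388.1	8111	281	Polymerase PBI	-
nrEVE_EdiaRhabdo_8	E. diana	JXPB01060825.1	762	1104	Capsid	-
nrEVE_EdiaRhabdo_3	E. diana	JXPB01062097.1	1703	335	Hypothetical	-
nrEVE_EdiaParititi_1	E. diana	JXPB01069909.1	442	746	Capsid	-
nrEVE_EdiaVirga_1	E. diana	JXPB01074003.1	450	227	RdRp	-
nrEVE_EdiaRhabdo_9	E. diana	JXPB01076293.1	482	1115	Glycoprotein	-
nrEVE_EdiaRhabdo_10	E. diana	JXPB01076293.1	1657	2305	RdRp	-
nrEVE_EdiaTombus_1	E. diana	JXPB01078316.1	975	682	RdRp	-
nrEVE_EdiaXinmo_2	E. diana	JXPB01081550.1	1865	1308	RdRp	-
nrEVE_EdiaRhabdo_1	E. diana	JXPB01083515.1	1285	224	Capsid	-
nrEVE_EdiaXinmo_1	E. diana	JXPB01092275.1	1377	1193	Glycoprotein	-
nrEVE_EdiaPhenui_1	E. diana	JXPB01133418.1	21	248	Capsid	-
nrEVE_EdiaPhenui_2	E. diana	JXPB01133418.1	461	263	Capsid	-
nrEVE_EdiaOrthomyxo_1	E. diana	JXPB01138291.1	668	668	Capsid	-
nrEVE_EdiaPartiti_2	E. diana	JXPB01138318.1	851	213	Hypothetical	-
nrEVE_RzepPartiti_1	R. zephrya	NW_016157090.1	26347	1248	Capsid	-
nrEVE_RzepRhabdo_2	R. zephrya	NW_016157090.1	27492	7521	RdRp	-
nrEVE_RzepuncRib_1	R. zephrya	NW_016157156.1	16917	470	Capsid	-
nrEVE_RzepVirga_1	R. zephrya	NW_016157156.1	17688	179	Hypothetical	-
nrEVE_RzepPhasma_1	R. zephrya	NW_016157315.1	176535	281	Capsid	-
nrEVE_RzepPhasma_2	R. zephrya	NW_016157416.1	457	500	Capsid	-
nrEVE_RzepRhabdo_1	R. zephrya	NW_016203273.1	307	408	Capsid	-
nrEVE_RzepXinmo_1	R. zephrya	NW_016204950.1	724	650	Capsid	-
nrEVE_TcalPartiti_1	T. californica	JXPN01014811.1	1303	241	Capsid	-
nrEVE_TcalRhabdo_1	T. californica	JXPN01043797.1	48	890	Capsid	-
nrEVE_TcalOrthomyxo_1	T. californica	JXPN01049893.1	3	224	Capsid	-
nrEVE_TcaluncRib_1	T. californica	JXPN01093879.1	9	713	Hypothetical	-
nrEVE_TcalPhasma_1	T. californica	JXPN01108971.1	252	848	Capsid	-
nrEVE_TjonToti_1	T. jonesi	JXQA01001198.1	1315	221	Capsid	-
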