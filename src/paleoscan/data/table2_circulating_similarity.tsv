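name	accession	length	query_cover	evalue	identity	virus
nrEVE_BcucNarna_1	NW_011863697.1	221	72%	2E-34	78.88%	Ceratitis capitata narnavirus
nrEVE_BlatRhabdo_1	NW_017537113.1	485	86%	2E-101	79.19%	Ceratitis capitata sigmavirus
nrEVE_BlatRhabdo_1	NW_017537113.1	485	74%	9E-49	72.33%	Bactrocera tryoni rhabdovirus 1
nrEVE_BlatRhabdo_1	NW_017537113.1	485	71%	5E-40	70.49%	Bactrocera dorsalis sigmavirus
nrEVE_BtryRhabdo_2	JHQJ01003828.1	701	66%	3E-25	65.89%	Ceratitis capitata sigmavirus
nrEVE_CcapRhabdo_1	NW_019378575.1	629	60%	5E-22	66.24%	Ceratitis capitata sigmavirus
nrEVE_EdiaXinmo_2	JXPB01081550.1	1308	89%	2E-120	67.85%	Bactrocera dorsalis xinmovirus 2
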