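nlr_id	status	taestivum	hvulgare	atauschii	hvillosa_arm
Hv_Contig_60_nlr_3	Complete NLR	1D	1H	1D	1VS
Hv_Contig_138_nlr_2	Complete NLR	1A	1H	1D	1VS
Hv_Contig_140_nlr_1	Complete NLR	1D	1H	1D	1VS
Hv_Contig_232_nlr_1	Complete NLR	1B	1H	1D	1VS
Hv_Contig_443_nlr_1	Complete NLR	1B	1H	1D	1VS
Hv_Contig_992_nlr_1	Complete NLR	1A	1H	1D	1VS
Hv_Contig_1391_nlr_1	Complete NLR	1A	1H	1D	1VS
Hv_Contig_254_nlr_1	Complete NLR	1A	1H	1D	1VL
Hv_Contig_452_nlr_1	Complete NLR	1D	1H	1D	1VL
Hv_Contig_1453_nlr_1	Complete NLR	1D	1H	1D	1VL
Hv_Contig_951	Partial or pseudogene	1A	3H	1D	1VS
Hv_Contig_1193	Partial or pseudogene	1D	1H	1D	1VS
Hv_Contig_141	Partial or pseudogene	1A	1H	1D	1VL
Hv_Contig_219	Partial or pseudogene	1D	1H	1D	1VL
Hv_Contig_512_nlr_1	Complete NLR	2A	2H	2D	2VS
Hv_Contig_544_nlr_2	Complete NLR	2D	2H	2D	2VS
Hv_Contig_223_nlr_1	Complete NLR	2B	2H	2D	2VL
Hv_Contig_1028_nlr_1	Complete NLR	2D	2H	2D	2VL
Hv_Contig_461_nlr_1	Complete NLR	2D	2H	2D	2VL
Hv_Contig_1254	Partial or pseudogene	Un	2H	2D	2VS
Hv_Contig_35	Partial or pseudogene	2D	2H	2D	2VL
Hv_Contig_139	Partial or pseudogene	2D	2H	2D	2VL
Hv_Contig_667	Partial or pseudogene	2B	2H	2D	2VL
Hv_Contig_716_nlr_1	Complete NLR	3A	3H	3D	3VS
Hv_Contig_782_nlr_1	Complete NLR	3B	3H	3D	3VS
Hv_Contig_11_nlr_1	Complete NLR	3D	3H	3D	3VL
Hv_Contig_79_nlr_1	Complete NLR	3B	3H	3D	3VL
Hv_Contig_326_nlr_1	Complete NLR	3D	3H	3D	3VL
Hv_Contig_657_nlr_2	Complete NLR	3A	3H	3D	3VL
Hv_Contig_866_nlr_1	Complete NLR	3B	3H	3D	3VL
Hv_Contig_77	Partial or pseudogene	3A	3H	3D	3VL
Hv_Contig_686	Partial or pseudogene	3B	3H	3D	3VL
Hv_Contig_90_nlr_1	Complete NLR	4B	Un	4D	4VS
Hv_Contig_116_nlr_1	Complete NLR	4D	4H	4D	4VS
Hv_Contig_322_nlr_2	Complete NLR	4B	4H	4D	4VS
Hv_Contig_670_nlr_1	Complete NLR	4B	4H	4D	4VS
Hv_Contig_28_nlr_1	Complete NLR	7B	7H	7D	4VL
Hv_Contig_55_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_82_nlr_2	Complete NLR	7D	7H	7D	4VL
Hv_Contig_172_nlr_1	Complete NLR	7B	7H	7D	4VL
Hv_Contig_299_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_393_nlr_1	Complete NLR	7A	7H	7D	4VL
Hv_Contig_648_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_798_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_913_nlr_2	Complete NLR	7D	7H	7D	4VL
Hv_Contig_958_nlr_1	Complete NLR	7B	7H	7D	4VL
Hv_Contig_1239_nlr_1	Complete NLR	7A	7H	7D	4VL
Hv_Contig_1300_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_1318_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_1410_nlr_1	Complete NLR	7D	7H	7D	4VL
Hv_Contig_120	Partial or pseudogene	4B	4H	4D	4VS
Hv_Contig_362	Partial or pseudogene	4A	7H	7D	4VL
Hv_Contig_1235	Partial or pseudogene	7A	2H	7D	4VL
Hv_Contig_1339	Partial or pseudogene	4A	7H	7D	4VL
Hv_Contig_541_nlr_1	Complete NLR	5D	5H	5D	5VS
Hv_Contig_1146_nlr_1	Complete NLR	7D	5H	7D	5VS
Hv_Contig_105_nlr_1	Complete NLR	5D	5H	5D	5VL
Hv_Contig_253_nlr_1	Complete NLR	5A	5H	5D	5VL
Hv_Contig_308_nlr_1	Complete NLR	5B	5H	7D	5VL
Hv_Contig_705_nlr_1	Complete NLR	5D	5H	5D	5VL
Hv_Contig_757_nlr_1	Complete NLR	5D	5H	5D	5VL
Hv_Contig_937_nlr_1	Complete NLR	5B	Un	5D	5VL
Hv_Contig_950_nlr_1	Complete NLR	5B	5H	5D	5VL
Hv_Contig_85	Partial or pseudogene	5B	5H	2D	5VS
Hv_Contig_270	Partial or pseudogene	5B	5H	5D	5VL
Hv_Contig_1353	Partial or pseudogene	5A	5H	6D	5VL
Hv_Contig_665_nlr_1	Complete NLR	6B	6H	6D	6VS
Hv_Contig_39_nlr_2	Complete NLR	6B	6H	6D	6VS
Hv_Contig_249_nlr_2	Complete NLR	6B	6H	6D	6VS
Hv_Contig_514_nlr_1	Complete NLR	6D	6H	6D	6VL
Hv_Contig_750_nlr_1	Complete NLR	6B	6H	5D	6VL
Hv_Contig_860_nlr_1	Complete NLR	6A	6H	6D	6VL
Hv_Contig_1012	Partial or pseudogene	6A	6H	6D	6VS
Hv_Contig_1162	Partial or pseudogene	6B	6H	Un	6VS
Hv_Contig_736	Partial or pseudogene	6D	Un	6D	6VS
Hv_Contig_539	Partial or pseudogene	6B	6H	6D	6VL
Hv_Contig_38_nlr_2	Complete NLR	7A	7H	7D	7VS
Hv_Contig_55_nlr_1	Complete NLR	7D	7H	7D	7VS
Hv_Contig_99_nlr_3	Complete NLR	7D	7H	7D	7VL
Hv_Contig_508_nlr_1	Complete NLR	4A	7H	3D	7VL
Hv_Contig_1010_nlr_1	Complete NLR	7B	Un	7D	7VL
Hv_Contig_1236_nlr_1	Complete NLR	7D	7H	7D	7VL
Hv_Contig_632	Partial or pseudogene	7B	7H	7D	7VS
Hv_Contig_912	Partial or pseudogene	7A	7H	7D	7VS
Hv_Contig_414	Partial or pseudogene	4A	7H	7D	7VL
Hv_Contig_940	Partial or pseudogene	7D	7H	7D	7VL
Hv_Contig_978	Partial or pseudogene	7A	4H	7D	7VL
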