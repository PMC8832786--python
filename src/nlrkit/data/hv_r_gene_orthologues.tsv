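r_gene	anchor	subject_mb	nlr_id	in_silico_location	nlr_type	protein_length	identity	coverage
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_1079_nlr_1	1V	CNL	967	86.7	86.0
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_343_nlr_1	1V	CNL	960	86.6	86.3
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_1392_nlr_1	1V	CNL	955	86.9	86.0
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_1173_nlr_1	1V	CNL	949	86.0	88.2
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_1386_nlr_1	1V	CNL	954	85.4	84.2
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_857_nlr_1	1V	CNL	973	85.0	84.1
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_60_nlr_2	1V	CNL	866	87.8	87.9
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_212_nlr_1	1V	CNL	951	87.9	86.2
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_115_nlr_1	1V	CNL	941	87.4	83.5
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_653_nlr_1	1V	CNL	882	87.5	85.9
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_1211_nlr_1	1V	CNL	880	86.4	79.3
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_605_nlr_1	1V	CNL	886	87.5	79.8
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_181_nlr_1	1V	CNL	967	86.6	88.0
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_1213_nlr_1	1V	CNL	895	85.1	86.4
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_436_nlr_1	1V	CNL	966	85.9	84.7
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_188_nlr_1	1V	CNL	913	85.8	80.4
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_298_nlr_1	1V	CNL	955	84.7	85.9
Mla1/Sr50	Mla_1H_30.2Mb	30.2	Hv_Contig_650_nlr_1	1V	CNL	883	84.8	86.0
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_751_nlr_1	1V	CNL	921	84.7	78.6
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_1287_nlr_1	1V	CNL	932	86.3	67.1
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_947_nlr_1	1V	CNL	948	85.7	78.1
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_678_nlr_2	1V	CNL	967	85.7	68.1
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_178_nlr_1	1V	CNL	967	85.8	87.7
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_1150_nlr_1	1V	CNL	937	81.3	82.4
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_785_nlr_1	1V	CNL	859	85.8	69.0
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_399_nlr_1	1V	CNL	959	87.3	75.8
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_422_nlr_1	1V	CNL	943	87.5	78.0
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_727_nlr_1	1V	CNL	767	84.4	70.0
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_559_nlr_1	1V	CNL	745	80.1	73.5
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_238_nlr_1	1V	CNL	964	84.8	63.9
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_668_nlr_1	1V	CNL	909	84.5	85.0
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_119_nlr_2	1V	CNL	947	80.5	91.1
Mla1/Sr50	Mla_1H_8.6Mb	8.6	Hv_Contig_924_nlr_1	1V	CNL	947	84.9	84.9
Pm3b			Hv_Contig_1461_nlr_1	1V	CNL	1422	91.5	93.4
Pm3b			Hv_Contig_1202_nlr_1	1V	CNL	1525	90.1	100
Pm3b			Hv_Contig_1215_nlr_1	1V	CNL	1473	90.4	93.7
Pm3b			Hv_Contig_1186_nlr_1	1V	CNL	1485	84.7	96.9
Sr45			Hv_Contig_1433_nlr_1	1V	CNL	1204	91.6	65.2
Sr45			Hv_Contig_1007_nlr_1	1V	CNL	1156	91.6	61.6
Sr45			Hv_Contig_232_nlr_1	1V	CNL	1219	84.1	73.1
Yr7			Hv_Contig_909_nlr_1	2V	CC-zf-BED-NL	1509	80.0	82.0
Yr7			Hv_Contig_430_nlr_1	2V	zf-BED-NL	1417	74.5	91.3
RCR1			Hv_Contig_1205_nlr_1	3V	CNL	943	87.8	96.6
Sr35			Hv_Contig_191_nlr_1	3V	CNL	922	89.5	67.0
Sr35			Hv_Contig_479_nlr_1	3V	CNL	918	84.3	78.2
Lr1			Hv_Contig_1032_nlr_1	5V	CNL	872	86.3	73.6
Lr1			Hv_Contig_1499_nlr_1	5V	NL	1169	86.1	71.2
Lr1			Hv_Contig_582_nlr_1	5V	CNL	1392	85.3	77.6
Pm2			Hv_Contig_335_nlr_1	5V	CNL	1260	93.0	99.8
Pm2			Hv_Contig_1045_nlr_1	5V	CNL	1230	86.1	89.4
Pm2			Hv_Contig_810_nlr_1	5V	CNL	1053	80.1	86.0
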