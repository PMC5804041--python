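sample_id	imf_percent	gebv	group	mapped_reads
High_01	4.42	0.44	H	676705.83
High_02	4.12	0.51	H	722149.21
High_03	4.35	0.57	H	856445.98
High_04	5.02	0.47	H	564721.48
High_05	4.74	0.81	H	1477652.40
High_06	3.99	0.51	H	382812.08
High_07	4.17	0.66	H	1372859.97
High_08	4.95	0.59	H	714291.96
High_09	3.97	0.57	H	637211.41
High_10	4.38	0.71	H	628643.15
High_11	5.27	0.85	H	803295.42
High_12	4.35	0.61	H	675159.48
High_13	3.75	0.42	H	610860.91
High_14	2.99	0.36	H	327429.32
High_15	4.13	0.81	H	578590.62
Low_01	2.06	-0.57	L	681969.11
Low_02	1.32	-0.77	L	825926.83
Low_03	1.35	-0.36	L	654790.36
Low_04	1.70	-0.31	L	510809.28
Low_05	1.44	-0.51	L	661870.55
Low_06	1.04	-0.33	L	675033.41
Low_07	1.58	-0.50	L	711330.33
Low_08	1.39	-0.52	L	421474.63
Low_09	1.94	-0.29	L	727950.69
Low_10	1.86	-0.24	L	980827.28
Low_11	1.38	-0.43	L	754990.11
Low_12	1.60	-0.59	L	655706.88
Low_13	1.62	-0.57	L	862654.84
Low_14	0.65	-0.22	L	821821.32
Low_15	1.69	-0.27	L	1398620.62
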