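library	platform	method	library_build	avg_read_length	raw_reads	percent_mapped
Barley1a	HiSeq2500/pe/125 bp	target enrichment	ds	92	9363464	0.008
Barley1b	Miseq/pe/75 bp	target enrichment	ss	78	4052951	0.029
Barley2a	HiSeq2500/pe/125 bp	target enrichment	ds	100	6943249	0.007
Barley2b	Miseq/pe/75 bp	target enrichment	ss	76	4577402	0.040
Barley3a	HiSeq2500/pe/125 bp	shotgun	ds	80	1445024	0.010
Barley3b	Miseq/pe/75 bp	shotgun	ss	72	5006428	0.022
Barley4a	HiSeq2500/pe/125 bp	shotgun	ds	95	6406123	0.008
Barley4b	Miseq/pe/75 bp	shotgun	ss	83	353474	0.014
Barley5	Miseq/pe/75 bp	target enrichment	ss	69	3641058	0.123
Barley6	Miseq/pe/75 bp	target enrichment	ss	68	3031164	0.085
Barley7	Miseq/pe/75 bp	shotgun	ss	68	2384691	0.076
Barley8	Miseq/pe/75 bp	shotgun	ss	78	639883	0.015
Grape1	HiSeq2500/se/100 bp	shotgun	ds	69	6337515	0.003
Grape2	HiSeq2500/se/100 bp	shotgun	ds	72	8657842	0.003
Grape3	HiSeq2500/se/81 bp	shotgun	ds	72	6491713	0.008
Grape4	HiSeq2500/se/81 bp	shotgun	ds	67	9147375	0.009
Grape5	HiSeq2500/se/81 bp	shotgun	ds	66	5794427	0.015
Maize1	HiSeq2500/se/81 bp	shotgun	ds	72	5052523	0.006
Maize2	HiSeq2500/se/81 bp	shotgun	ds	73	7351039	0.007
Maize3	HiSeq2500/se/81 bp	shotgun	ds	67	135982	0.011
Maize4	HiSeq2500/se/81 bp	shotgun	ds	65	10742918	0.013
Maize5	HiSeq2500/se/81 bp	shotgun	ds	66	7822641	0.016
Maize6	HiSeq2500/se/81 bp	shotgun	ds	67	7645073	0.012
Maize7	HiSeq2500/se/81 bp	shotgun	ds	67	6588747	0.007
Maize8a	HiSeq2500/se/100 bp	shotgun	ds	72	28239900	0.026
Maize8b	HiSeq2500/se/100 bp	target enrichment	ds	78	21895732	0.016
Rice1	MiSeq/se/250 bp	target enrichment WG	ds	193	390515	0.005
Rice2	MiSeq/se/250 bp	target enrichment	ds	63	500538	0.015
Rice3	MiSeq/se/250 bp	target enrichment SS	ds	141	1783367	0.001
Rice4	MiSeq/se/250 bp	target enrichment WG	ds	228	499372	0.001
Rice5	MiSeq/se/250 bp	target enrichment SS	ds	114	4953182	0.001
Rice6	MiSeq/se/250 bp	target enrichment WG	ds	219	567506	0.002
Rice7	MiSeq/se/250 bp	target enrichment SS	ds	131	6101994	0.001
Rice8	MiSeq/se/250 bp	target enrichment WG	ds	194	447690	0.002
Rice9	MiSeq/se/250 bp	target enrichment WG	ds	227	301980	0.002
Rice10	MiSeq/se/250 bp	target enrichment SS	ds	177	3425508	0.000
Rice11	MiSeq/se/250 bp	target enrichment WG	ds	172	592182	0.013
Rice12a	MiSeq/se/250 bp	shotgun	ds	206	2608916	0.000
Rice12b	MiSeq/se/250 bp	target enrichment WG	ds	179	1476971	0.001
Rice13	MiSeq/se/250 bp	target enrichment	ds	70	396830	0.012
Rice14	MiSeq/se/250 bp	target enrichment	ds	74	1096766	0.018
Rice15	MiSeq/se/250 bp	target enrichment	ds	78	595556	0.006
Rice16	MiSeq/se/250 bp	target enrichment	ds	64	338135	0.009
Rice17	MiSeq/se/250 bp	target enrichment	ds	93	373420	0.002
Blank_barley1	HiSeq2500/se/81 bp	shotgun	ds	54	33740465	NA
Blank_barley2	HiSeq2500/se/81 bp	shotgun	ds	66	7126362	NA
Blank_barley3	HiSeq2500/se/81 bp	shotgun	ds	68	671521	NA
Blank_grape1	HiSeq2500/se/100 bp	shotgun	ds	58	33090380	NA
Blank_maize1	HiSeq2500/se/100 bp	shotgun	ds	52	43339302	NA
Blank_maize2	HiSeq2500/se/81 bp	shotgun	ds	71	15727571	NA
Blank_rice1	MiSeq/se/250 bp	shotgun	ds	91	250044	NA
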