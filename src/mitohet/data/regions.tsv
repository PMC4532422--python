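# rCRS (NC_012920) gene-region annotation, 1-based inclusive coordinates.
# Rows with parent "." form a strict partition of positions 1..16569 (the control
# region MT-CR wraps across the origin: 16024..16569 plus 1..576).  Overlapping
# CDS/tRNA starts of the standard annotation (MT-TQ, MT-TY, MT-ATP6, MT-CO3,
# MT-ND4) are trimmed so that every base belongs to exactly one row; the "frame"
# column preserves the true reading frame of trimmed protein genes, defined so
# that codon phase of position p on the heavy strand is (p - start + frame) % 3
# (for light-strand genes, (end - p + frame) % 3).  Intergenic spacers (MT-NC*)
# and the light-strand replication origin (MT-OL) are carried as control-class
# rows.  Rows with a parent are sub-features used for labelling only
# (hypervariable segments and their homopolymeric C-stretches).
name	start	end	region_class	strand	frame	parent
MT-CR	16024	576	control	+	0	.
MT-TF	577	647	tRNA	+	0	.
MT-RNR1	648	1601	rRNA	+	0	.
MT-TV	1602	1670	tRNA	+	0	.
MT-RNR2	1671	3229	rRNA	+	0	.
MT-TL1	3230	3304	tRNA	+	0	.
MT-NC1	3305	3306	control	+	0	.
MT-ND1	3307	4262	protein	+	0	.
MT-TI	4263	4331	tRNA	+	0	.
MT-TQ	4332	4400	tRNA	-	0	.
MT-NC2	4401	4401	control	+	0	.
MT-TM	4402	4469	tRNA	+	0	.
MT-ND2	4470	5511	protein	+	0	.
MT-TW	5512	5579	tRNA	+	0	.
MT-NC3	5580	5586	control	+	0	.
MT-TA	5587	5655	tRNA	-	0	.
MT-NC4	5656	5656	control	+	0	.
MT-TN	5657	5729	tRNA	-	0	.
MT-OL	5730	5760	control	+	0	.
MT-TC	5761	5826	tRNA	-	0	.
MT-TY	5827	5891	tRNA	-	0	.
MT-NC5	5892	5903	control	+	0	.
MT-CO1	5904	7445	protein	+	0	.
MT-TS1	7446	7514	tRNA	-	0	.
MT-NC6	7515	7517	control	+	0	.
MT-TD	7518	7585	tRNA	+	0	.
MT-CO2	7586	8269	protein	+	0	.
MT-NC7	8270	8294	control	+	0	.
MT-TK	8295	8364	tRNA	+	0	.
MT-NC8	8365	8365	control	+	0	.
MT-ATP8	8366	8572	protein	+	0	.
MT-ATP6	8573	9207	protein	+	1	.
MT-CO3	9208	9990	protein	+	1	.
MT-TG	9991	10058	tRNA	+	0	.
MT-ND3	10059	10404	protein	+	0	.
MT-TR	10405	10469	tRNA	+	0	.
MT-ND4L	10470	10766	protein	+	0	.
MT-ND4	10767	12137	protein	+	1	.
MT-TH	12138	12206	tRNA	+	0	.
MT-TS2	12207	12265	tRNA	+	0	.
MT-TL2	12266	12336	tRNA	+	0	.
MT-ND5	12337	14148	protein	+	0	.
MT-ND6	14149	14673	protein	-	0	.
MT-TE	14674	14742	tRNA	-	0	.
MT-NC9	14743	14746	control	+	0	.
MT-CYB	14747	15887	protein	+	0	.
MT-TT	15888	15953	tRNA	+	0	.
MT-NC10	15954	15955	control	+	0	.
MT-TP	15956	16023	tRNA	-	0	.
HVS-I	16024	16365	control	+	0	MT-CR
HVS-II	73	340	control	+	0	MT-CR
HVS-III	438	574	control	+	0	MT-CR
HVS-I-CSTRETCH	16184	16193	control	+	0	HVS-I
HVS-II-CSTRETCH	303	315	control	+	0	HVS-II
HVS-III-CSTRETCH	568	573	control	+	0	HVS-III
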