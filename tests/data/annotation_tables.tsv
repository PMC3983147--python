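table	label	chrom	start	end	strand	coverage
1	RefSeq_BMPR1A	6	3546262	3585602	+	39340
1	ENSGALT00000003119	6	3546283	3585813	+	39530
1	proposed_5UTR	6	3546262	3564179	+	17917
1	proposed_body	6	3564180	3585585	+	21405
1	proposed_3UTR	6	3585586	3590064	+	4478
2	RefSeq_HOXA7	2	32570322	32572159	-	1837
2	ENSGALT00000018013	2	32570285	32571987	-	1702
2	proposed_5UTR	2	32572160	32572292	-	132
2	proposed_body	2	32570322	32572159	-	1837
2	proposed_3UTR	2	32568768	32570321	-	1553
3	RefSeq_SLFN5	17	33570086	33594768	+	24682
3	ENST00000299977	17	33570055	33600674	+	30619
3	ENST00000542451	17	33570090	33593379	+	23289
3	ENST00000299977_short	17	33570108	33586839	+	16731
3	proposed_5UTR	17	33570055	33585708	+	15653
3	proposed_body	17	33585709	33592121	+	6412
3	proposed_3UTR_1	17	33592121	33597113	+	4992
3	proposed_3UTR_2	17	33592121	33600669	+	8548
4	TAIR10_AT4G02715	4	1203279	1202169	-	1110
4	proposed_5UTR	4	1203279	1202998	-	281
4	proposed_body	4	1202998	1202169	-	829
4	proposed_3UTR_2	4	1202169	1200688	-	1481
4	proposed_3UTR_3	4	1202169	1200666	-	1503
5	TAIR10_AT1G68945	1	25926962	25927330	+	368
5	proposed_5UTR	1	25927329	25927314	-	15
5	proposed_body	1	25927313	25927167	-	146
8	TAIR10_AT4G10810	4	6646335	6645715	-	620
8	automated_reannotation	4	6646335	6645421	-	914
8	proposed_5UTR	4	6646335	6646229	-	106
8	proposed_body	4	6646230	6645984	-	246
8	novel_snoRNA	4	6645422	6645529	-	107
8	predicted_snoRNA	4	6645420	6645538	-	118
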