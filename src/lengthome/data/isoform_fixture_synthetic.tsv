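# Synthetic worked-example gene models for the nine switching genes.
# Coordinates are constructed (the true genomic coordinates are not public);
# region lengths, S/L/= codes and mechanism classes reproduce the published
# per-gene values exactly (e.g. Mta3 3'UTR 93 -> 820 nt, CDS 1542 -> 1757 nt).
transcript_id	gene_symbol	chrom	strand	exon_starts	exon_ends	cds_start_tx	cds_end_tx
NM_001037955	Dusp22	ctg_Dusp22	+	1,1001	600,2200	101	1102
NM_134068	Dusp22	ctg_Dusp22	+	1,1001,3001	600,1500,3300	101	901
NM_001164037	Ly6e	ctg_Ly6e	+	1,1001	200,2500	501	1400
NM_001164038	Ly6e	ctg_Ly6e	+	1,1101	200,2500	401	1300
NM_001164040	Ly6e	ctg_Ly6e	+	1,1201	200,2500	301	1200
NM_001171053	Mta3	ctg_Mta3	+	1,2001	1000,2735	101	1642
NM_001171052	Mta3	ctg_Mta3	+	1,2001,4001	1000,2614,5063	101	1857
NM_177466	Rab11fip5	ctg_Rab11fip5	+	1,2001,4001	500,2800,4600	101	1600
NM_001003955	Rab11fip5	ctg_Rab11fip5	+	1,1001,2001,4001	500,1150,2800,4600	101	1750
NM_001166623	Rbmx	ctg_Rbmx	+	1,1001	300,2200	401	1300
NM_011252	Rbmx	ctg_Rbmx	+	1,1004	300,2200	398	1297
NM_001163757	Skor	ctg_Skor	+	1,1001	400,1900	201	800
NM_001163758	Skor	ctg_Skor	+	51,1001	400,1900	301	750
NM_001079694	Srsf5	ctg_Srsf5	+	1,1001	250,2350	301	1200
NM_009159	Srsf5	ctg_Srsf5	+	1,1005	250,2350	297	1196
NM_001042708	Ilf3	ctg_Ilf3	+	1,1001,3001	400,1800,4400	151	1350
NM_001042707	Ilf3	ctg_Ilf3	+	1,1001,5001	400,1800,5900	151	1650
NM_027557	Pwwp2a	ctg_Pwwp2a	+	1,2001	800,3200	121	1620
NM_001164231	Pwwp2a	ctg_Pwwp2a	+	1,2001,4001	800,2500,5000	121	1320
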