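# RefSeq genes on the grey brocket deer B regions with completeness flags:
# complete, f = partial fragment at a region margin, fq = overlapping a
# putative deletion ("(f?)").  Regions keyed by (chrom, start).
gene_id	region_chrom	region_start	flag
LPP	chr1	80557678	f
PIK3CB	chr1	132195520	f
GFI1	chr3	53939956	complete
ACOT11	chr3	97346492	f
SSBP3	chr3	97346492	f
CCND2	chr5	112038039	complete
COX7B2	chr6	67475289	complete
GABRA4	chr6	67475289	complete
GABRB1	chr6	67475289	fq
LOC536190	chr6	67475289	fq
ATP10D	chr6	67475289	complete
NFXL1	chr6	67475289	complete
CNGA1	chr6	67475289	complete
NIPAL1	chr6	67475289	complete
TXK	chr6	67475289	complete
KIT	chr6	72725708	f
COQ2	chr6	101762919	complete
HPSE	chr6	101762919	complete
MIR2446	chr6	101762919	complete
MRPS18C	chr6	101762919	complete
FAM175A	chr6	101762919	f
MIR2448	chr6	115148215	complete
FBXL5	chr6	115148215	complete
CD38	chr6	115148215	fq
FGFBP1	chr6	115148215	complete
MAN2B1	chr7	11112904	f
ANXA10	chr8	78145	complete
MIR2466	chr8	78145	complete
TMCO5B	chr10	28363651	complete
KHDRBS3	chr14	5823596	f
MBD3L1	chr17	46546364	complete
CHFR	chr17	46546364	complete
ZNF268	chr17	46546364	f
CDC42EP4	chr19	59129525	complete
FAM104A	chr19	59129525	complete
COG1	chr19	59129525	f
EOMES	chr22	1765826	f
ACAA1	chr22	11626319	complete
MYD88	chr22	11626319	complete
OXSR1	chr22	11626319	complete
XYLB	chr22	11626319	complete
ACVR2B	chr22	11626319	complete
DLEC1	chr22	11626319	f
C23H6orf106	chr23	8994141	f
SNRPC	chr23	8994141	f
SERPINB9	chr23	50678412	complete
TRIM67	chr28	628155	complete
FAM89A	chr28	628155	complete
ARV1	chr28	628155	complete
TTC13	chr28	628155	f
RET	chr28	12110619	complete
OPCML	chr29	34728621	f
DHCR7	chr29	49338779	fq
NADSYN1	chr29	49338779	complete
CARS	chr29	49338779	f
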