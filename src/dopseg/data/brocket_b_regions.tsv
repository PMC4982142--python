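# Genomic regions homologous to grey brocket deer B chromosomes,
# cattle assembly bosTau7 coordinates (26 regions, 23 kbp - 1.83 Mbp).
chrom	start	end
chr1	80557678	80815945
chr1	132195520	132248825
chr3	53939956	54035661
chr3	97346492	97530439
chr5	112038039	112092762
chr6	67475289	69302666
chr6	72725708	72802304
chr6	101762919	101983089
chr6	115148215	115688073
chr7	11112904	11187619
chr7	21377048	21645864
chr8	78145	782808
chr10	28363651	29133083
chr14	5823596	6377396
chr17	46546364	46775437
chr19	59129525	59366644
chr22	1765826	1920639
chr22	11626319	11984586
chr23	8994141	9084277
chr23	50678412	50701238
chr25	37085021	37276232
chr25	41480442	41787784
chr28	628155	915003
chr28	12110619	12174951
chr29	34728621	35503130
chr29	49338779	50252639
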