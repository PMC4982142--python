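# Genomic regions homologous to Siberian roe deer B chromosomes,
# cattle assembly bosTau7 coordinates.
chrom	start	end
chr3	74548027	76486586
chr28	11359721	11400841
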