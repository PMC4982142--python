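# Putative internal deletions (stretches not covered by reads) within the
# chr3 roe-deer B region, bosTau7 coordinates.  The second coincides with a
# cattle assembly gap.
chrom	start	end	overlaps_assembly_gap
chr3	74880000	75300000	0
chr3	75680000	75820000	1
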