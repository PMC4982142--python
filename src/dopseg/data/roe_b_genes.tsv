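# RefSeq genes on the roe-deer B regions with completeness flags:
# complete, f = partial fragment at a region margin, fq = overlapping a
# putative deletion ("(f?)").
gene_id	region_chrom	region_start	flag
LRRIQ3	chr3	74548027	complete
FPGT	chr3	74548027	complete
TNNI3K	chr3	74548027	f
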