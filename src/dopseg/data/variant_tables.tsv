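# Per-sample variant accounting inputs (bosTau7 / cattle RefSeq):
# covered_bp = length of read-covered sequence in the feature class,
# n_all / n_het = called variants (all / heterozygous) in the class.
# Samples: BTAMix = mixed cattle autosome peak; CPYB = roe-deer B reads;
# CPYB_CCA = CPYB minus variants shared with European roe deer contigs;
# MGOB = brocket-deer B reads.  Class counts overlap (multiple annotations
# per variant), so classes need not sum to the total.
sample	category	covered_bp	n_all	n_het
BTAMix	total	6068678	19188	6374
BTAMix	intergenic	4518518	14829	4970
BTAMix	intron	1501565	4556	1474
BTAMix	utr5	1337	4	2
BTAMix	utr3	15213	49	18
BTAMix	coding	32045	90	23
CPYB	total	344775	15267	2915
CPYB	intergenic	262448	12187	2349
CPYB	intron	80987	3134	558
CPYB	utr5	0	0	0
CPYB	utr3	0	0	0
CPYB	coding	1340	43	13
CPYB_CCA	total	297042	3086	1929
CPYB_CCA	intergenic	226421	2476	1530
CPYB_CCA	intron	69282	605	392
CPYB_CCA	utr5	0	0	0
CPYB_CCA	utr3	0	0	0
CPYB_CCA	coding	1339	13	10
MGOB	total	1332441	46592	1735
MGOB	intergenic	991640	35292	1334
MGOB	intron	327012	10102	320
MGOB	utr5	27	2	0
MGOB	utr3	2780	101	8
MGOB	coding	10982	216	14
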