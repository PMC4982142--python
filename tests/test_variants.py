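"""Callset algebra, covered-feature sizes, densities, effect classification."""

import numpy as np
import pandas as pd
import pytest

from dopseg import deer
from dopseg.variants import (
    CoveredFeatureSizes,
    GeneModel,
    covered_feature_sizes,
    classify_callset,
    classify_effect,
    het_hom_ratio,
    novelty_stats,
    read_bed12,
    read_vcf,
    subtract_callsets,
    variant_density,
    variant_density_from_counts,
    write_vcf,
)


def make_callset(n, rng, chrom="chr1", het_frac=0.4, start=1):
    pos = np.arange(start, start + n) * 10
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, n)) % 4]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "zygosity": np.where(rng.random(n) < het_frac, "het", "hom"),
            "depth": rng.integers(1, 20, n),
        }
    )


# ---------------------------------------------------------------------------
# subtraction


def test_subtract_self_is_empty(rng):
    a = make_callset(100, rng)
    assert len(subtract_callsets(a, a)) == 0


def test_subtract_disjoint_unchanged(rng):
    a = make_callset(100, rng)
    b = make_callset(50, rng, start=10_000)
    out = subtract_callsets(a, b)
    pd.testing.assert_frame_equal(out.reset_index(drop=True), a)


def test_subtract_partial_overlap_set_oracle(rng):
    """|A - B| = 300 when B holds 200 of A's 500 plus 100 novel."""
    a = make_callset(500, rng)
    b_from_a = a.sample(200, random_state=1)
    b_novel = make_callset(100, rng, start=50_000)
    b = pd.concat([b_from_a, b_novel], ignore_index=True)
    out = subtract_callsets(a, b)
    key = lambda df: {(c, p, r, t) for c, p, r, t in zip(df.chrom, df.pos, df.ref, df.alt)}
    assert len(out) == 300
    assert key(out) == key(a) - key(b)


def test_subtract_contig_mismatch_raises(rng):
    a = make_callset(10, rng, chrom="chr1")
    b = make_callset(10, rng, chrom="scaffold_77")
    with pytest.raises(ValueError, match="share no contigs"):
        subtract_callsets(a, b)


# ---------------------------------------------------------------------------
# covered feature sizes


def simple_gene(chrom="chr1", start=1000, end=9000, strand="+"):
    # two exons, CDS within them, UTRs at both ends
    return GeneModel(
        gene_id="G1",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=[(start, start + 2000), (end - 3000, end)],
        cds_start=start + 500,
        cds_end=end - 500,
    )


def test_covered_sizes_wholly_intronic_interval():
    g = simple_gene()
    sizes = covered_feature_sizes([("chr1", 3500, 4500)], [g])
    assert sizes.intron == 1000
    assert sizes.total == 1000
    assert sizes.coding == sizes.utr5 == sizes.utr3 == sizes.intergenic == 0


def test_covered_sizes_empty_coverage():
    sizes = covered_feature_sizes([], [simple_gene()])
    assert sizes.total == 0 and sizes.intergenic == 0


def test_covered_sizes_partition_by_direct_interval_arithmetic():
    g = simple_gene()  # gene 1000-9000; exon1 1000-3000, exon2 6000-9000; CDS 1500-8500
    cov = [("chr1", 0, 10_000)]
    sizes = covered_feature_sizes(cov, [g])
    assert sizes.utr5 == 500  # 1000-1500
    assert sizes.utr3 == 500  # 8500-9000
    assert sizes.coding == (3000 - 1500) + (8500 - 6000)
    assert sizes.intron == 6000 - 3000
    assert sizes.intergenic == 10_000 - 8000
    assert sizes.total == 10_000


def test_covered_sizes_strand_swaps_utrs():
    g = simple_gene(strand="-")
    sizes = covered_feature_sizes([("chr1", 0, 10_000)], [g])
    assert sizes.utr3 == 500 and sizes.utr5 == 500  # symmetric fixture


# ---------------------------------------------------------------------------
# density and ratios


def test_density_total_from_catalog_counts():
    """6,068,678 covered bp / 19,188 variants -> 316 bp per variant."""
    table = variant_density_from_counts(
        {"total": 6_068_678}, {"total": 19_188}, {"total": 6_374}
    )
    assert table.density_all["total"] == 316
    assert table.density_het["total"] == 952


def test_density_reduced_callset_counts():
    table = variant_density_from_counts(
        {"total": 297_042}, {"total": 3_086}, {"total": 1_929}
    )
    assert table.density_all["total"] == 96
    assert table.density_het["total"] == 154


def test_density_zero_variants_undefined():
    table = variant_density_from_counts({"total": 1_000}, {"total": 0}, {"total": 0})
    assert table.density_all["total"] is None


def test_density_from_classified_callset(rng):
    sizes = CoveredFeatureSizes(
        total=10_000, intergenic=6_000, intron=3_000, utr5=0, utr3=0, coding=1_000
    )
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": range(1, 41),
            "ref": "A",
            "alt": "G",
            "zygosity": ["het", "hom"] * 20,
            "depth": 10,
            "effect": ["intergenic"] * 30 + ["intron"] * 6 + ["coding_syn"] * 2
            + ["coding_nonsyn"] * 2,
        }
    )
    table = variant_density(sizes, variants)
    assert table.density_all["total"] == 250  # 10000/40
    assert table.density_all["intergenic"] == 200
    assert table.density_all["coding"] == 250  # 1000/4
    assert table.density_het["total"] == 500


def test_het_hom_ratio_catalog_counts():
    """6,374 het of 19,188 total -> 0.50 at two decimals."""
    v = pd.DataFrame({"zygosity": ["het"] * 6_374 + ["hom"] * (19_188 - 6_374)})
    assert round(het_hom_ratio(v), 2) == 0.50


def test_het_hom_ratio_all_het_undefined():
    v = pd.DataFrame({"zygosity": ["het"] * 10})
    assert het_hom_ratio(v) is None


def test_het_hom_ratio_planted_exactly_recovered(rng):
    v = make_callset(400, rng, het_frac=0.0)
    v.loc[: 99, "zygosity"] = "het"  # 100 het / 300 hom
    assert het_hom_ratio(v) == pytest.approx(100 / 300)


def test_novelty_counts(rng):
    a = make_callset(300, rng)
    known = a.sample(90, random_state=2)  # 30% known -> 70% novel
    stats = novelty_stats(a, known, min_depth=0)
    assert stats["n_total"] == 300
    assert stats["n_novel"] == 210
    assert stats["pct_novel"] == pytest.approx(70.0)


def test_novelty_empty_known_is_all_novel(rng):
    a = make_callset(50, rng)
    stats = novelty_stats(a, a.iloc[0:0])
    assert stats["pct_novel"] == 100.0


def test_novelty_depth_filter_applied_first(rng):
    a = make_callset(200, rng)
    a["depth"] = [3] * 100 + [8] * 100
    stats = novelty_stats(a, a.iloc[0:0], min_depth=4)
    assert stats["n_total"] == 100


# ---------------------------------------------------------------------------
# effect classification


@pytest.fixture
def mini_genome():
    # gene on chr1:100-400, single exon, CDS 100-400 (100 codons), + strand
    cds = "ATG" + "GCT" * 98 + "TAA"  # Met, 98x Ala, stop
    seq = "T" * 100 + cds + "T" * 600
    gene = GeneModel("GENE1", "chr1", 100, 400, "+", [(100, 400)], 100, 400)
    return {"chr1": seq}, gene


def test_synonymous_third_position(mini_genome):
    ref_map, gene = mini_genome
    # codon 2 occupies 103-106 = GCT; third position T->C keeps Ala
    v = {"chrom": "chr1", "pos": 106, "ref": "T", "alt": "C"}
    assert classify_effect(v, [gene], ref_map) == "coding_syn"


def test_missense_first_position(mini_genome):
    ref_map, gene = mini_genome
    v = {"chrom": "chr1", "pos": 104, "ref": "G", "alt": "T"}  # Ala -> Ser
    assert classify_effect(v, [gene], ref_map) == "coding_nonsyn"


def test_frameshift_deletion_is_nonsyn(mini_genome):
    ref_map, gene = mini_genome
    v = {"chrom": "chr1", "pos": 104, "ref": ref_map["chr1"][103:105], "alt": ref_map["chr1"][103]}
    assert classify_effect(v, [gene], ref_map) == "coding_nonsyn"


def test_far_from_genes_is_intergenic(mini_genome):
    ref_map, gene = mini_genome
    v = {"chrom": "chr1", "pos": 650, "ref": ref_map["chr1"][649], "alt": "A" if ref_map["chr1"][649] != "A" else "C"}
    assert classify_effect(v, [gene], ref_map) == "intergenic"


def test_ref_mismatch_raises(mini_genome):
    ref_map, gene = mini_genome
    base = ref_map["chr1"][105]
    wrong = "A" if base != "A" else "G"
    with pytest.raises(ValueError, match="disagrees with reference"):
        classify_effect({"chrom": "chr1", "pos": 106, "ref": wrong, "alt": "C"}, [gene], ref_map)


def test_minus_strand_synonymy():
    # same CDS placed on the minus strand: plus-strand sequence is its revcomp
    from Bio.Seq import Seq

    cds = "ATG" + "GCT" * 8 + "TAA"
    plus = "A" * 50 + str(Seq(cds).reverse_complement()) + "A" * 50
    gene = GeneModel("GENE2", "chr1", 50, 50 + len(cds), "-", [(50, 50 + len(cds))], 50, 50 + len(cds))
    ref_map = {"chr1": plus}
    # third codon position of the 2nd codon (GCT): genomic base index
    # minus-strand CDS pos 5 (0-based) maps to plus index 50+len(cds)-1-5
    g_idx = 50 + len(cds) - 1 - 5
    ref = plus[g_idx]  # complement of T = A
    v = {"chrom": "chr1", "pos": g_idx + 1, "ref": ref, "alt": "G"}  # T->C on cds strand
    assert classify_effect(v, [gene], ref_map) == "coding_syn"


# ---------------------------------------------------------------------------
# VCF round trip and BED12


def test_vcf_round_trip(tmp_path, rng):
    df = make_callset(20, rng)
    path = tmp_path / "calls.vcf"
    write_vcf(df, path, {"chr1": 10_000_000})
    back = read_vcf(path)
    pd.testing.assert_frame_equal(
        back[["chrom", "pos", "ref", "alt", "zygosity"]],
        df[["chrom", "pos", "ref", "alt", "zygosity"]],
    )


def test_read_bed12_blocks(tmp_path):
    line = "chr1\t1000\t9000\tG1\t0\t+\t1500\t8500\t0\t2\t2000,3000\t0,5000\n"
    p = tmp_path / "genes.bed"
    p.write_text(line)
    (g,) = read_bed12(p)
    assert g.exons == [(1000, 3000), (6000, 9000)]
    assert (g.cds_start, g.cds_end) == (1500, 8500)


def test_catalog_variant_table_headline_densities():
    """All six printed bp-per-variant totals reproduce from the catalog inputs."""
    tbl = deer.load_variant_tables()
    tot = tbl[tbl["category"] == "total"].set_index("sample")
    expect = {"BTAMix": (316, 952), "CPYB": (23, 118), "CPYB_CCA": (96, 154), "MGOB": (29, 768)}
    for sample, (d_all, d_het) in expect.items():
        row = tot.loc[sample]
        table = variant_density_from_counts(
            {"total": int(row["covered_bp"])},
            {"total": int(row["n_all"])},
            {"total": int(row["n_het"])},
        )
        assert table.density_all["total"] == d_all
        assert table.density_het["total"] == d_het
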