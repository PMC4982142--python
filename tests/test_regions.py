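"""Segment classification, region margins, deletions, gene completeness."""

import numpy as np
import pandas as pd
import pytest

from dopseg import deer
from dopseg.regions import (
    annotate_genes,
    call_regions,
    classify_segments,
    detect_deletions,
    region_size_accounting,
    scan_small_candidates,
)


def seg_frame(rows):
    """rows: (chrom, first, last, start, end, n, mean_pd)."""
    return pd.DataFrame(
        [
            {
                "chrom": c,
                "first_idx": f,
                "last_idx": l,
                "start_bp": s,
                "end_bp": e,
                "n_positions": n,
                "mean_pd": m,
                "segment_stat": np.log2(m + 1),
                "trivial": False,
            }
            for c, f, l, s, e, n, m in rows
        ]
    )


def test_clear_bimodality_classified():
    segs = seg_frame(
        [
            ("chr1", 0, 99, 0, 200_000, 100, 2_000),
            ("chr1", 100, 199, 200_000, 420_000, 100, 2_200),
            ("chr2", 0, 99, 0, 4_000_000, 100, 40_000),
            ("chr3", 0, 99, 0, 4_500_000, 100, 45_000),
        ]
    )
    labeled = classify_segments(segs)
    assert labeled["label"].tolist() == ["target", "target", "background", "background"]


def test_no_contrast_all_background_with_warning():
    segs = seg_frame(
        [("chr%d" % i, 0, 99, 0, 10**6, 100, 40_000 * (1 + 0.02 * i)) for i in range(5)]
    )
    with pytest.warns(UserWarning, match="no target/background contrast"):
        labeled = classify_segments(segs)
    assert (labeled["label"] == "background").all()


def test_single_segment_genome_is_background():
    segs = seg_frame([("chr1", 0, 99, 0, 10**6, 100, 40_000)])
    with pytest.warns(UserWarning, match="single segment"):
        labeled = classify_segments(segs)
    assert labeled["label"].tolist() == ["background"]


def test_threshold_method():
    segs = seg_frame(
        [("chr1", 0, 9, 0, 10_000, 10, 1_000), ("chr1", 10, 19, 10_000, 10**6, 10, 50_000)]
    )
    labeled = classify_segments(segs, method="threshold", mean_pd_cutoff=5_000)
    assert labeled["label"].tolist() == ["target", "background"]


def test_small_terminal_target_segment_demoted_to_ambiguous():
    """Telomeric-artifact rule: few positions at a chromosome end."""
    segs = seg_frame(
        [
            ("chr10", 0, 5, 4_993_000, 4_999_800, 6, 500),  # 6 positions at the end
            ("chr3", 0, 399, 1_000_000, 3_000_000, 400, 2_000),
            ("chr3", 400, 499, 3_000_000, 8_000_000, 100, 40_000),
            ("chr2", 0, 99, 0, 4_000_000, 100, 41_000),
        ]
    )
    labeled = classify_segments(segs, chrom_lengths={"chr10": 5_000_000})
    by = dict(zip(labeled["chrom"] + ":" + labeled["first_idx"].astype(str), labeled["label"]))
    assert by["chr10:0"] == "ambiguous"
    assert by["chr3:0"] == "target"


def test_adjacent_target_segments_merge_into_one_region():
    segs = seg_frame(
        [
            ("chr1", 0, 99, 1_000_000, 1_200_000, 100, 1_800),
            ("chr1", 100, 199, 1_200_500, 1_500_000, 100, 2_600),
            ("chr1", 200, 299, 1_500_500, 9_000_000, 100, 40_000),
            ("chr2", 0, 99, 0, 4_000_000, 100, 42_000),
        ]
    )
    labeled = classify_segments(segs)
    calls = call_regions(labeled)
    assert len(calls) == 1
    row = calls.iloc[0]
    assert (row["start"], row["end"], row["n_positions"]) == (1_000_000, 1_500_000, 200)


def test_no_target_segments_no_regions():
    segs = seg_frame([("chr1", 0, 99, 0, 10**6, 100, 40_000)])
    with pytest.warns(UserWarning):
        labeled = classify_segments(segs)
    assert len(call_regions(labeled)) == 0


def test_roe_catalog_regions_sum():
    """The two roe-deer intervals reconstructed from fixture positions."""
    regions = deer.load_roe_regions()
    acct = region_size_accounting(regions)
    assert acct["total_bp"] == 1_979_679


def test_detect_deletions_fully_covered_region_empty():
    regions = deer.load_roe_regions()
    pos = deer.synthetic_positions(regions, deletions=[])
    r3 = regions[regions["chrom"] == "chr3"].iloc[0]
    assert detect_deletions(r3, pos) == []


def test_detect_deletions_roe_coordinates():
    """Positions removed in 74.88-75.30 Mbp -> one 420 kbp call; the second
    (140 kbp) deletion is annotated with its assembly-gap overlap."""
    regions = deer.load_roe_regions()
    dels = deer.load_roe_deletions(regions)
    pos = deer.synthetic_positions(regions, dels)
    r3 = regions[regions["chrom"] == "chr3"].iloc[0]
    calls = detect_deletions(r3, pos, gaps=[("chr3", 75_700_000, 75_810_000)])
    assert [(c.start, c.end) for c in calls] == [
        (74_880_000, 75_300_000),
        (75_680_000, 75_820_000),
    ]
    assert [c.length for c in calls] == [420_000, 140_000]
    assert [c.overlaps_assembly_gap for c in calls] == [False, True]


def test_detect_deletions_brocket_total():
    """10 planted uncovered stretches totalling 1.03 Mbp -> 10 calls."""
    regions = deer.load_brocket_regions()
    dels = deer.synthetic_brocket_deletions(regions)
    pos = deer.synthetic_positions(regions, dels)
    calls = []
    for _, row in regions.iterrows():
        calls.extend(detect_deletions(row, pos))
    assert len(calls) == 10
    assert sum(c.length for c in calls) == 1_030_000


def test_deletions_stay_inside_regions_and_disjoint():
    regions = deer.load_brocket_regions()
    dels = deer.synthetic_brocket_deletions(regions)
    pos = deer.synthetic_positions(regions, dels)
    for _, row in regions.iterrows():
        calls = detect_deletions(row, pos)
        prev_end = None
        for c in calls:
            assert row["start"] < c.start and c.end < row["end"]
            if prev_end is not None:
                assert c.start >= prev_end
            prev_end = c.end


def test_gene_status_simple_cases():
    regions = pd.DataFrame(
        [{"region_id": "R1", "chrom": "chr1", "start": 0, "end": 100_000,
          "n_positions": 50, "mean_pd": 2000, "label": "target"}]
    )
    genes = pd.DataFrame(
        [
            {"gene_id": "inside", "chrom": "chr1", "start": 10_000, "end": 20_000},
            {"gene_id": "crossing", "chrom": "chr1", "start": 95_000, "end": 110_000},
            {"gene_id": "outside", "chrom": "chr1", "start": 200_000, "end": 210_000},
        ]
    )
    calls, summary = annotate_genes(regions, [], genes)
    status = {c.gene_id: c.status for c in calls}
    assert status == {"inside": "complete", "crossing": "partial_margin"}
    assert summary["n_complete"] == 1 and summary["n_partial"] == 1


def test_margin_beats_deletion_tiebreak():
    from dopseg.regions import DeletionCall

    regions = pd.DataFrame(
        [{"region_id": "R1", "chrom": "chr1", "start": 0, "end": 100_000,
          "n_positions": 50, "mean_pd": 2000, "label": "target"}]
    )
    dels = [DeletionCall("chr1", 90_000, 99_000, "R1")]
    genes = pd.DataFrame(
        [{"gene_id": "both", "chrom": "chr1", "start": 95_000, "end": 110_000}]
    )
    calls, _ = annotate_genes(regions, dels, genes)
    assert calls[0].status == "partial_margin"


def test_brocket_gene_completeness_counts():
    """Catalog flags realised as intervals: 34 complete + 21 partial genes."""
    regions = deer.load_brocket_regions()
    dels = deer.synthetic_brocket_deletions(regions)
    genes = deer.synthetic_gene_models(regions, deer.load_gene_flags("brocket"), dels)
    _, summary = annotate_genes(regions, dels, genes)
    assert summary["n_complete"] == 34
    assert summary["n_partial"] == 21
    assert summary["n_partial_deletion"] == 4


def test_region_size_accounting_roe_abstract_range():
    regions = deer.load_roe_regions()
    dels = deer.load_roe_deletions(regions)
    acct = region_size_accounting(regions, dels)
    assert acct["total_bp"] == 1_979_679
    assert round(acct["total_minus_deletions_bp"] / 1e6, 2) == 1.42


def test_region_size_accounting_empty():
    empty = pd.DataFrame(columns=["region_id", "chrom", "start", "end"])
    assert region_size_accounting(empty) == {"total_bp": 0, "total_minus_deletions_bp": 0}


def test_small_candidate_runs_outside_regions_reported():
    from dopseg.positions import PdSeries

    gaps = [40_000] * 10 + [1_000] * 5 + [40_000] * 10
    starts, ends, cur = [], [], 0
    for g in gaps:
        cur += g
        starts.append(cur)
        cur += 100
        ends.append(cur)
    series = PdSeries(
        "chr9", np.array(starts, np.int64), np.array(ends, np.int64),
        np.array(gaps, np.int64),
    )
    pos = pd.DataFrame(
        {"chrom": "chr9", "start": series.starts, "end": series.ends, "read_count": 1}
    )
    cands = scan_small_candidates([series], pos, pd_threshold=5_000, min_run=3)
    assert len(cands) == 1
    assert cands.iloc[0]["n_positions"] == 5
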