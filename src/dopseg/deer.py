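"""Catalogs for the deer B-chromosome case studies, plus fixture builders.

The package ships small plain-text tables with the cattle-genome (bosTau7)
coordinates of the regions homologous to Siberian roe deer and grey brocket
deer B chromosomes, the roe-deer putative deletions, the gene completeness
flags, and the per-sample variant accounting inputs (covered bp and variant
counts per feature class).  These serve as worked examples and as exact
arithmetic fixtures.

Gene *coordinates* are not part of the catalog (only names and flags are);
:func:`synthetic_gene_models` therefore constructs synthetic gene intervals
whose placement realises the recorded flags — complete genes inside the
region, "(f)" genes across a margin, "(f?)" genes over a deletion.  The
brocket deletion catalog is likewise synthetic: only the count (10) and
total (1.03 Mbp) are recorded, so :func:`synthetic_brocket_deletions` plants
ten 103-kbp stretches inside the larger regions, covering every "(f?)" gene's
region.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals
from .regions import DeletionCall

_DATA = Path(__file__).parent / "data"


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(_DATA / name, sep="\t", comment="#")


def _region_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "region_id", [f"R{i + 1}" for i in range(len(out))])
    out["label"] = "target"
    return out


def load_roe_regions() -> pd.DataFrame:
    return _region_frame(_read("roe_b_regions.tsv"))


def load_brocket_regions() -> pd.DataFrame:
    return _region_frame(_read("brocket_b_regions.tsv"))


def load_roe_deletions(regions: Optional[pd.DataFrame] = None) -> List[DeletionCall]:
    regions = load_roe_regions() if regions is None else regions
    out = []
    for _, row in _read("roe_b_deletions.tsv").iterrows():
        rid = _region_id_at(regions, row["chrom"], int(row["start"]))
        out.append(
            DeletionCall(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                region_id=rid,
                overlaps_assembly_gap=bool(row["overlaps_assembly_gap"]),
            )
        )
    return out


def load_gene_flags(sample: str) -> pd.DataFrame:
    """Gene completeness flags; ``sample`` is 'roe' or 'brocket'."""
    return _read(f"{sample}_b_genes.tsv")


def load_variant_tables() -> pd.DataFrame:
    """Covered-bp and variant-count inputs per sample and feature class."""
    return _read("variant_tables.tsv")


def _region_id_at(regions: pd.DataFrame, chrom, pos: int) -> str:
    hit = regions[
        (regions["chrom"].astype(str) == str(chrom))
        & (regions["start"] <= pos)
        & (regions["end"] > pos)
    ]
    if len(hit) == 0:
        raise ValueError(f"no region at {chrom}:{pos}")
    return str(hit.iloc[0]["region_id"])


# 10 synthetic deletions x 103 kbp = 1.03 Mbp, keyed by (chrom, region start,
# offset into the region).  Regions with "(f?)" genes all receive one.
_BROCKET_DELETION_PLAN: List[Tuple[str, int, int]] = [
    ("chr6", 67475289, 200_000),
    ("chr6", 67475289, 700_000),
    ("chr6", 67475289, 1_300_000),
    ("chr6", 115148215, 200_000),
    ("chr29", 49338779, 300_000),
    ("chr29", 34728621, 250_000),
    ("chr10", 28363651, 250_000),
    ("chr8", 78145, 250_000),
    ("chr14", 5823596, 200_000),
    ("chr6", 101762919, 60_000),
]
_BROCKET_DELETION_LEN = 103_000


def synthetic_brocket_deletions(regions: Optional[pd.DataFrame] = None) -> List[DeletionCall]:
    """Ten synthetic 103-kbp uncovered stretches inside brocket regions (1.03 Mbp)."""
    regions = load_brocket_regions() if regions is None else regions
    out = []
    for chrom, r_start, offset in _BROCKET_DELETION_PLAN:
        s = r_start + offset
        out.append(
            DeletionCall(
                chrom=chrom,
                start=s,
                end=s + _BROCKET_DELETION_LEN,
                region_id=_region_id_at(regions, chrom, s),
            )
        )
    return out


def synthetic_gene_models(
    regions: pd.DataFrame,
    gene_flags: pd.DataFrame,
    deletions: Sequence[DeletionCall] = (),
) -> pd.DataFrame:
    """Synthetic gene intervals realising the catalog's completeness flags.

    complete -> fully inside the region, clear of deletions; f -> crossing a
    region margin (alternating left/right); fq -> inside the region,
    overlapping one of the region's deletions.  Returns a gene_models frame
    (gene_id, chrom, start, end).
    """
    dels_by_region: Dict[str, List[DeletionCall]] = {}
    for d in deletions:
        dels_by_region.setdefault(d.region_id, []).append(d)

    rows = []
    for _, region in regions.iterrows():
        rid = str(region["region_id"])
        chrom = str(region["chrom"])
        r_s, r_e = int(region["start"]), int(region["end"])
        r_len = r_e - r_s
        sub = gene_flags[
            (gene_flags["region_chrom"].astype(str) == chrom)
            & (gene_flags["region_start"] == r_s)
        ]
        if len(sub) == 0:
            continue
        w = max(2000, min(10_000, r_len // 6))
        r_dels = sorted(dels_by_region.get(rid, []), key=lambda d: d.start)

        # interior slots for complete genes: region minus margins and deletions
        buffer = max(w, r_len // 20)
        interior = [(r_s + buffer, r_e - buffer)]
        if r_dels:
            interior = [
                tuple(iv)
                for iv in _intervals.subtract(
                    interior, [(d.start - w, d.end + w) for d in r_dels]
                )
            ]
        slots = []
        for s, e in interior:
            cur = s
            while cur + w <= e:
                slots.append((cur, cur + w))
                cur += 2 * w

        n_complete_total = int((sub["flag"] == "complete").sum())
        if n_complete_total > len(slots):
            raise RuntimeError(
                f"region {rid}: {n_complete_total} complete genes but only {len(slots)} slots"
            )
        chosen = (
            np.linspace(0, len(slots) - 1, n_complete_total).round().astype(int)
            if n_complete_total
            else np.array([], dtype=int)
        )
        # spread genes across the region; fall back to consecutive slots on ties
        if len(np.unique(chosen)) < n_complete_total:
            chosen = np.arange(n_complete_total)
        complete_slots = [slots[i] for i in chosen]

        n_margin = 0
        n_del = 0
        n_complete = 0
        for _, g in sub.iterrows():
            flag = str(g["flag"])
            if flag == "complete":
                start, end = complete_slots[n_complete]
                n_complete += 1
            elif flag == "f":
                if n_margin % 2 == 0:  # across the left margin
                    start, end = r_s - w // 2, r_s + w // 2
                else:  # across the right margin
                    start, end = r_e - w // 2, r_e + w // 2
                n_margin += 1
            elif flag == "fq":
                if not r_dels:
                    raise RuntimeError(f"region {rid}: fq gene but no deletion")
                d = r_dels[n_del % len(r_dels)]
                mid = (d.start + d.end) // 2
                start, end = mid - w // 2, mid + w // 2
                n_del += 1
            else:
                raise ValueError(f"unknown flag {flag!r}")
            rows.append({"gene_id": str(g["gene_id"]), "chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def synthetic_positions(
    regions: pd.DataFrame,
    deletions: Sequence[DeletionCall] = (),
    spacing: int = 2000,
    length: int = 150,
) -> pd.DataFrame:
    """Synthetic DOP-position table covering regions except their deletions.

    Positions are placed every ``spacing`` bp; the first position starts at
    each region's start and the last ends exactly at its end, so margins
    reconstructed from these positions reproduce the catalog coordinates.
    """
    del_ivs: Dict[str, list] = {}
    for d in deletions:
        del_ivs.setdefault(d.chrom, []).append((d.start, d.end))
    rows = []
    for _, region in regions.iterrows():
        chrom = str(region["chrom"])
        r_s, r_e = int(region["start"]), int(region["end"])
        live = _intervals.subtract([(r_s, r_e)], del_ivs.get(chrom, []))
        for s, e in live:
            cur = s
            while cur + length <= e:
                rows.append((chrom, cur, cur + length, 2))
                cur += spacing
            rows.append((chrom, e - length, e, 2))  # pin the right edge
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "read_count"])
    # pinning can create overlaps with the previous position; merge them
    from .positions import merge_reads_to_positions

    merged = merge_reads_to_positions(
        list(zip(df["chrom"], df["start"], df["end"]))
    )
    return merged
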