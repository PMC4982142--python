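"""Target-region calling from CBS segments.

Segments whose mean PD sits in the low mode of the genome-wide distribution
are candidates for being *target* — physically present on the sorted
chromosome.  This module labels segments (2-means on log mean PD, or a plain
threshold), merges adjacent target segments into regions whose margins are
the outermost retained positions, calls *putative deletions* (long internal
stretches with no read-covered position), annotates gene completeness
(complete / partial at a margin "(f)" / overlapping a deletion "(f?)") and
sums region sizes.  The classifier is a provisional tool: an ambiguous band
around the cluster boundary and sub-threshold candidate runs are surfaced
for visual review rather than silently decided.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals

REGION_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "n_positions",
    "mean_pd",
    "label",
]


@dataclasses.dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    region_id: str
    overlaps_assembly_gap: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class GeneCall:
    gene_id: str
    region_id: str
    status: str  # complete | partial_margin | partial_deletion


def classify_segments(
    segments: pd.DataFrame,
    method: str = "two_cluster",
    mean_pd_cutoff: Optional[float] = None,
    margin_factor: float = 2.0,
    min_contrast: float = 4.0,
    min_region_positions: int = 10,
    chrom_lengths: Optional[Dict[str, int]] = None,
    end_window: int = 100_000,
) -> pd.DataFrame:
    """Label segments as target / background / ambiguous.

    two_cluster: 1-D 2-means on log2(mean_pd); the low-mean cluster is
    target.  Segments whose mean PD lies within ``margin_factor`` of the
    geometric cluster boundary are flagged ambiguous for visual review.  If
    the two cluster centres differ by less than ``min_contrast`` (linear
    ratio) there is no real contrast and everything is background (with a
    warning).  threshold: a user-supplied ``mean_pd_cutoff`` decides.

    Short segments (< ``min_region_positions`` positions) at chromosome ends
    are demoted to ambiguous — spurious mapping of telomeric DNA produces
    exactly such artifacts.
    """
    df = segments.copy()
    if len(df) == 0:
        df["label"] = pd.Series(dtype=object)
        return df
    if method not in ("two_cluster", "threshold"):
        raise ValueError("method must be 'two_cluster' or 'threshold'")

    if method == "threshold":
        if mean_pd_cutoff is None:
            raise ValueError("threshold method needs mean_pd_cutoff")
        df["label"] = np.where(df["mean_pd"] < mean_pd_cutoff, "target", "background")
    else:
        logs = np.log2(df["mean_pd"].to_numpy(dtype=float) + 1.0)
        if len(df) == 1:
            warnings.warn("single segment genome-wide: no contrast, all background")
            df["label"] = "background"
            return df
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(logs.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        low_cluster = int(np.argmin(centers))
        c_low, c_high = sorted(centers)
        if 2.0 ** (c_high - c_low) < min_contrast:
            warnings.warn(
                "segment mean PDs show no target/background contrast; all background"
            )
            df["label"] = "background"
            return df
        boundary = (c_low + c_high) / 2.0
        is_target = km.labels_ == low_cluster
        ambiguous = np.abs(logs - boundary) < np.log2(margin_factor)
        df["label"] = np.where(
            is_target & ~ambiguous,
            "target",
            np.where(ambiguous, "ambiguous", "background"),
        )

    # telomeric-artifact suppression: tiny target segments at chromosome ends
    small = (df["label"] == "target") & (df["n_positions"] < min_region_positions)
    for idx in df.index[small]:
        chrom = str(df.at[idx, "chrom"])
        near_start = df.at[idx, "start_bp"] < end_window
        near_end = False
        if chrom_lengths and chrom in chrom_lengths:
            near_end = df.at[idx, "end_bp"] > chrom_lengths[chrom] - end_window
        if near_start or near_end:
            df.at[idx, "label"] = "ambiguous"
    return df


def call_regions(
    labeled_segments: pd.DataFrame,
    positions: Optional[pd.DataFrame] = None,
    margin_gap_factor: float = 2.0,
) -> pd.DataFrame:
    """Merge adjacent target segments per chromosome into region calls.

    Region margins start as the outermost retained positions of the merged
    segments.  When the full position table is given, margins are refined
    against it: the PD value of a region's first position is the large entry
    gap from the background, so CBS systematically places that position in
    the background segment, and outlier trimming can drop edge positions
    altogether.  Refinement walks outward over *all* positions while the gap
    stays within ``margin_gap_factor`` times the region's mean PD — i.e.
    while the local spacing still looks target-like.  Returns a
    Table-3-style frame sorted by (chrom, start).
    """
    rows = []
    if len(labeled_segments) == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)
    for chrom, grp in labeled_segments.groupby("chrom", sort=True):
        grp = grp.sort_values("first_idx").reset_index(drop=True)
        run: List[int] = []
        for i in range(len(grp) + 1):
            is_target = i < len(grp) and grp.at[i, "label"] == "target"
            adjacent = (
                bool(run) and i < len(grp)
                and grp.at[i, "first_idx"] == grp.at[run[-1], "last_idx"] + 1
            )
            if is_target and (not run or adjacent):
                run.append(i)
                continue
            if run:
                sub = grp.loc[run]
                n = int(sub["n_positions"].sum())
                rows.append(
                    {
                        "chrom": str(chrom),
                        "start": int(sub["start_bp"].min()),
                        "end": int(sub["end_bp"].max()),
                        "n_positions": n,
                        "mean_pd": float(
                            (sub["mean_pd"] * sub["n_positions"]).sum() / n
                        ),
                        "label": "target",
                    }
                )
                run = []
            if is_target:
                run.append(i)
    out = pd.DataFrame(rows, columns=[c for c in REGION_COLUMNS if c != "region_id"])
    if positions is not None and len(out):
        out = _refine_margins(out, positions, margin_gap_factor)
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "region_id", [f"R{i + 1}" for i in range(len(out))])
    return out


def _refine_margins(
    regions_df: pd.DataFrame,
    positions: pd.DataFrame,
    margin_gap_factor: float,
    stray_gap_factor: float = 8.0,
    stray_max_run: int = 10,
) -> pd.DataFrame:
    """Two-pass margin refinement against the full position table.

    Shrink pass: a terminal run of fewer than ``stray_max_run`` positions
    separated from the region core by a gap exceeding ``stray_gap_factor``
    times the region's mean PD is a stray background cluster, not a margin —
    at target density such a gap would contain dozens of positions, whereas
    a genuine internal deletion is followed by a long run.  Extend pass:
    walk outward while the spacing stays target-like (within
    ``margin_gap_factor`` of the mean PD), recovering edge positions whose
    PD values (the large entry gap) put them in the background segment.
    """
    out = regions_df.copy()
    for idx, row in out.iterrows():
        chrom = str(row["chrom"])
        sub = positions[positions["chrom"].astype(str) == chrom].sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        if len(starts) == 0:
            continue
        mean_pd = float(row["mean_pd"])
        s, e = int(row["start"]), int(row["end"])

        # --- shrink stray terminal runs
        inside = np.flatnonzero((starts >= s) & (ends <= e))
        if len(inside) > 1:
            in_starts, in_ends = starts[inside], ends[inside]
            gaps = in_starts[1:] - in_ends[:-1]
            stray_gap = stray_gap_factor * mean_pd
            lo, hi = 0, len(inside) - 1
            while hi > lo:
                # terminal run at the left edge
                k = lo
                while k < hi and gaps[k] <= stray_gap:
                    k += 1
                if k < hi and (k - lo + 1) < stray_max_run:
                    lo = k + 1
                    continue
                # terminal run at the right edge
                k = hi
                while k > lo and gaps[k - 1] <= stray_gap:
                    k -= 1
                if k > lo and (hi - k + 1) < stray_max_run:
                    hi = k - 1
                    continue
                break
            s, e = int(in_starts[lo]), int(in_ends[hi])
            n_inside = hi - lo + 1
        else:
            n_inside = int(row["n_positions"])

        # --- extend over target-like spacing
        max_gap = max(1.0, margin_gap_factor * mean_pd)
        added = 0
        i = int(np.searchsorted(starts, s)) - 1
        while i >= 0 and 0 <= s - ends[i] <= max_gap:
            s = int(starts[i])
            added += 1
            i -= 1
        j = int(np.searchsorted(ends, e, side="right"))
        while j < len(starts) and 0 <= starts[j] - e <= max_gap:
            e = int(ends[j])
            added += 1
            j += 1
        out.at[idx, "start"] = s
        out.at[idx, "end"] = e
        out.at[idx, "n_positions"] = n_inside + added
    return out


def detect_deletions(
    region: pd.Series,
    positions: pd.DataFrame,
    gaps: Optional[Sequence[Tuple[str, int, int]]] = None,
    min_gap: int = 100_000,
) -> List[DeletionCall]:
    """Putative deletions: internal stretches >= min_gap with no position.

    ``region`` is one row of :func:`call_regions` output; ``positions`` the
    full DOP-position table.  An overlapping assembly gap is annotated as a
    possible explanation (unmappable sequence), not evidence of absence.
    Calls never extend past region margins and are disjoint by construction.
    """
    chrom, r_start, r_end = str(region["chrom"]), int(region["start"]), int(region["end"])
    if r_end - r_start < min_gap:
        return []
    sub = positions[
        (positions["chrom"].astype(str) == chrom)
        & (positions["end"] > r_start)
        & (positions["start"] < r_end)
    ].sort_values("start")
    covered = np.column_stack(
        [
            sub["start"].to_numpy(np.int64).clip(min=r_start),
            sub["end"].to_numpy(np.int64).clip(max=r_end),
        ]
    ) if len(sub) else np.empty((0, 2), dtype=np.int64)
    uncovered = _intervals.subtract([(r_start, r_end)], covered)

    gap_ivs = _intervals.as_interval_array(
        [(int(s), int(e)) for c, s, e in (gaps or []) if str(c) == chrom]
    )
    out = []
    for s, e in uncovered:
        if s <= r_start or e >= r_end:
            continue  # margins belong to positions; only internal stretches count
        if e - s < min_gap:
            continue
        overlaps_gap = bool(
            len(gap_ivs) and _intervals.intersect_length([(s, e)], gap_ivs) > 0
        )
        out.append(
            DeletionCall(
                chrom=chrom,
                start=int(s),
                end=int(e),
                region_id=str(region.get("region_id", "")),
                overlaps_assembly_gap=overlaps_gap,
            )
        )
    return out


def annotate_genes(
    regions: pd.DataFrame,
    deletions: Sequence[DeletionCall],
    gene_models: pd.DataFrame,
) -> Tuple[List[GeneCall], Dict[str, int]]:
    """Gene completeness per region: complete, (f) at margins, (f?) over deletions.

    ``gene_models`` needs columns gene_id, chrom, start, end.  A gene fully
    inside a region that does not touch a deletion is complete; a gene
    crossing a region margin is a partial fragment "(f)"; a gene inside the
    region but overlapping a putative deletion is "(f?)".  A gene both
    crossing a margin and a deletion resolves margin-first to "(f)".
    Only genes overlapping a region are reported.
    """
    dels_by_region: Dict[str, List[DeletionCall]] = {}
    for d in deletions:
        dels_by_region.setdefault(d.region_id, []).append(d)

    calls: List[GeneCall] = []
    for _, region in regions.iterrows():
        chrom = str(region["chrom"])
        r_s, r_e = int(region["start"]), int(region["end"])
        rid = str(region["region_id"])
        sub = gene_models[
            (gene_models["chrom"].astype(str) == chrom)
            & (gene_models["end"] > r_s)
            & (gene_models["start"] < r_e)
        ]
        for _, g in sub.iterrows():
            g_s, g_e = int(g["start"]), int(g["end"])
            crosses_margin = g_s < r_s or g_e > r_e
            hits_deletion = any(
                g_s < d.end and g_e > d.start for d in dels_by_region.get(rid, [])
            )
            if crosses_margin:
                status = "partial_margin"
            elif hits_deletion:
                status = "partial_deletion"
            else:
                status = "complete"
            calls.append(GeneCall(str(g["gene_id"]), rid, status))

    summary = {
        "n_genes": len(calls),
        "n_complete": sum(c.status == "complete" for c in calls),
        "n_partial_margin": sum(c.status == "partial_margin" for c in calls),
        "n_partial_deletion": sum(c.status == "partial_deletion" for c in calls),
    }
    summary["n_partial"] = summary["n_partial_margin"] + summary["n_partial_deletion"]
    return calls, summary


def region_size_accounting(
    regions: pd.DataFrame, deletions: Sequence[DeletionCall] = ()
) -> Dict[str, int]:
    """Total region bp and the total net of deletions (clipped to regions)."""
    total = int((regions["end"] - regions["start"]).sum()) if len(regions) else 0
    del_bp = 0
    for d in deletions:
        for _, r in regions.iterrows():
            if str(r["chrom"]) == d.chrom:
                s = max(d.start, int(r["start"]))
                e = min(d.end, int(r["end"]))
                if e > s:
                    del_bp += e - s
    return {"total_bp": total, "total_minus_deletions_bp": total - del_bp}


def scan_small_candidates(
    pd_series_list,
    positions: pd.DataFrame,
    pd_threshold: float,
    regions: Optional[pd.DataFrame] = None,
    min_run: int = 3,
) -> pd.DataFrame:
    """Secondary scan for sub-min_width candidate regions ("visual review").

    Runs of >= ``min_run`` consecutive positions with PD <= ``pd_threshold``
    outside any called region are reported as candidates — the counterpart of
    rescuing small regions by eye from the PD plot.
    """
    called: Dict[str, np.ndarray] = {}
    if regions is not None and len(regions):
        for chrom, grp in regions.groupby("chrom"):
            called[str(chrom)] = np.column_stack(
                [grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)]
            )
    rows = []
    for series in pd_series_list:
        low = series.pd <= pd_threshold
        i = 0
        n = len(low)
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= min_run:
                s, e = int(series.starts[i]), int(series.ends[j - 1])
                ivs = called.get(series.chrom)
                if ivs is None or _intervals.intersect_length([(s, e)], ivs) == 0:
                    rows.append(
                        {
                            "chrom": series.chrom,
                            "start": s,
                            "end": e,
                            "n_positions": j - i,
                            "label": "candidate (visual)",
                        }
                    )
            i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_positions", "label"])


def deletions_to_frame(deletions: Sequence[DeletionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "length": d.length,
                "region_id": d.region_id,
                "overlaps_assembly_gap": d.overlaps_assembly_gap,
            }
            for d in deletions
        ],
        columns=["chrom", "start", "end", "length", "region_id", "overlaps_assembly_gap"],
    )
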