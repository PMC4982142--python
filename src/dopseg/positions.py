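"""DOP-positions: merged read intervals, pairwise distances, occupancy.

Overlapping (or book-ended) reads are collapsed into *DOP-positions* — each
standing for one DOP-PCR amplicon locus.  For every chromosome the
*pairwise distance* (PD) of position ``i`` is the gap to the position on its
left, ``start_i - end_{i-1}``; the first position's PD is its distance to the
chromosome's 0-coordinate.  This gives the conservation identity

    sum(pd) + sum(position lengths) == end of last position

which is asserted throughout.  Low mean PD marks regions present on the
sorted chromosome.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals

POSITION_COLUMNS = ["chrom", "start", "end", "read_count"]


@dataclasses.dataclass
class PdSeries:
    """Ordered PD values of one chromosome, with the positions they belong to."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    pd: np.ndarray  # pd[i] = starts[i] - ends[i-1]; pd[0] = starts[0]

    def __len__(self) -> int:
        return len(self.pd)

    def check(self) -> None:
        if len(self.pd) != len(self.starts):
            raise ValueError("PD length != number of positions")
        lengths = self.ends - self.starts
        if len(self.pd) and int(self.pd.sum() + lengths.sum()) != int(self.ends[-1]):
            raise ValueError("PD conservation identity violated")


@dataclasses.dataclass
class OccupancyStats:
    """Genome-wide position counts and their relation to a target-region set.

    ``pct_positions_in_target`` — percent of all DOP-positions whose midpoint
    lies in a target region; ``occupancy_pct`` — percent of the target set's
    length covered by positions.  Target-relative fields are None (undefined,
    distinct from 0) when the target set is empty.
    """

    n_positions_genome: int
    bp_positions_genome: int
    target_region_bp: int
    pct_positions_in_target: Optional[float]
    occupancy_pct: Optional[float]
    positions_per_kbp_target: Optional[float]


def merge_reads_to_positions(read_intervals: Iterable[Tuple[str, int, int]]) -> pd.DataFrame:
    """Collapse read intervals into DOP-positions.

    Overlapping-or-book-ended intervals merge (BEDtools ``merge`` defaults);
    ``read_count`` is the number of contributing reads.  Records with
    ``end <= start`` are rejected with a per-record diagnostic.

    Returns a DataFrame with columns chrom, start, end, read_count sorted by
    (chrom, start).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    rejected = []
    for i, (chrom, start, end) in enumerate(read_intervals):
        if end <= start or start < 0:
            rejected.append((i, chrom, start, end))
            continue
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    if rejected:
        detail = "; ".join(f"record {i}: {c}:{s}-{e}" for i, c, s, e in rejected[:10])
        raise ValueError(f"{len(rejected)} invalid read interval(s): {detail}")

    rows = []
    for chrom in sorted(by_chrom):
        arr = np.asarray(by_chrom[chrom], dtype=np.int64)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        arr = arr[order]
        cur_s, cur_e, n = arr[0, 0], arr[0, 1], 1
        for s, e in arr[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
                n += 1
            else:
                rows.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        rows.append((chrom, cur_s, cur_e, n))
    return pd.DataFrame(rows, columns=POSITION_COLUMNS)


def compute_pd(
    positions: pd.DataFrame, chrom_lengths: Optional[Dict[str, int]] = None
) -> List[PdSeries]:
    """Per-chromosome PD series from a sorted, disjoint position table."""
    out = []
    for chrom, grp in positions.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        if np.any(np.diff(starts) < 0):
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: positions overlap; merge first")
        if chrom_lengths is not None:
            limit = chrom_lengths.get(str(chrom))
            if limit is not None and len(ends) and ends[-1] > limit:
                raise ValueError(
                    f"{chrom}: position end {int(ends[-1])} beyond chromosome length {limit}"
                )
        pd_vals = np.empty(len(starts), dtype=np.int64)
        if len(starts):
            pd_vals[0] = starts[0]  # distance to the 0-coordinate
            pd_vals[1:] = starts[1:] - ends[:-1]
        series = PdSeries(chrom=str(chrom), starts=starts, ends=ends, pd=pd_vals)
        series.check()
        out.append(series)
    return out


def position_length_histogram(
    positions: pd.DataFrame,
    bin_width: int = 10,
    min_prominence_frac: float = 0.1,
):
    """Histogram of DOP-position lengths plus detected modes.

    DOP amplicon lengths are characteristically bimodal (peaks near 100 bp
    and 180-200 bp under tagmentation library prep).  Modes are local maxima
    of the binned counts with prominence at least ``min_prominence_frac`` of
    the tallest bin; each mode is reported as the mean length within its bin
    so exact unimodal inputs give the exact value.

    Returns ``(hist: DataFrame[bin_start, bin_end, count], modes: list[float])``.
    """
    from scipy.signal import find_peaks

    lengths = (positions["end"] - positions["start"]).to_numpy()
    if len(lengths) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]), []
    lo = 0
    hi = int(np.ceil((lengths.max() + 1) / bin_width)) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
    # pad so peaks at the first/last bin are found
    padded = np.concatenate([[0], counts, [0]])
    peaks, _ = find_peaks(padded, prominence=max(1.0, min_prominence_frac * counts.max()))
    modes = []
    for p in peaks - 1:
        in_bin = lengths[(lengths >= edges[p]) & (lengths < edges[p + 1])]
        modes.append(float(in_bin.mean()))
    return hist, modes


def occupancy_stats(
    positions: pd.DataFrame,
    target_regions: Sequence[Tuple[str, int, int]],
) -> OccupancyStats:
    """Table-2-style statistics of positions relative to a target-region set.

    Membership of a position in a region is decided by its midpoint
    (positions are ~100-200 bp against multi-kbp regions, so edge effects are
    negligible); occupancy is exact interval intersection.
    """
    n_genome = len(positions)
    bp_genome = int((positions["end"] - positions["start"]).sum())

    targets_by_chrom: Dict[str, list] = {}
    for chrom, s, e in target_regions:
        targets_by_chrom.setdefault(str(chrom), []).append((int(s), int(e)))
    target_bp = sum(
        _intervals.total_length(_intervals.merge(iv)) for iv in targets_by_chrom.values()
    )

    if not targets_by_chrom:
        return OccupancyStats(n_genome, bp_genome, 0, None, None, None)

    n_in = 0
    inter_bp = 0
    for chrom, grp in positions.groupby("chrom"):
        ivs = targets_by_chrom.get(str(chrom))
        if not ivs:
            continue
        merged = _intervals.merge(ivs)
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy()
        for s, e in merged:
            n_in += int(((mid >= s) & (mid < e)).sum())
        pos_iv = np.column_stack(
            [grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)]
        )
        inter_bp += _intervals.intersect_length(pos_iv, merged)

    return OccupancyStats(
        n_positions_genome=n_genome,
        bp_positions_genome=bp_genome,
        target_region_bp=int(target_bp),
        pct_positions_in_target=100.0 * n_in / n_genome if n_genome else None,
        occupancy_pct=100.0 * inter_bp / target_bp if target_bp else None,
        positions_per_kbp_target=1000.0 * n_in / target_bp if target_bp else None,
    )


# ---------------------------------------------------------------------------
# IO (BED3+1: chrom, start, end, read_count)


def read_positions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=POSITION_COLUMNS, usecols=[0, 1, 2, 3],
    )
    return df


def write_positions_bed(df: pd.DataFrame, path) -> None:
    df.sort_values(["chrom", "start"]).to_csv(
        path, sep="\t", header=False, index=False, columns=POSITION_COLUMNS
    )


def read_chrom_sizes(path) -> Dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            out[chrom] = int(size)
    return out
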