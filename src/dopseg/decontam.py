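"""Dual-genome read decontamination.

Reads from DOP-PCR amplified sorted-chromosome libraries are aligned both to
the target genome (cattle or dog here) and to the ubiquitous contaminant,
human.  A read whose human alignment has a higher mapping quality than its
target alignment is treated as contamination and discarded; the survivors must
additionally clear a target-genome MAPQ floor (default: MAPQ > 20) so that
only unique, confident target alignments feed the position analysis.

The in-memory representation of a dual alignment is one pandas DataFrame row
with columns ``read_id, mate, target_mapq, contam_mapq, target_chrom,
target_start, target_end`` — missing alignments are NaN and are treated as
MAPQ 0 in comparisons.  Input may come from a pre-joined TSV or from two
SAM/BAM files joined on (read name, mate).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

TSV_COLUMNS = [
    "read_id",
    "mate",
    "target_mapq",
    "contam_mapq",
    "target_chrom",
    "target_start",
    "target_end",
]


@dataclasses.dataclass
class DecontamStats:
    """Partition of the input reads; mirrors the per-sample mapping statistics table."""

    n_input: int
    n_contaminant_removed: int
    n_lowq_removed: int
    n_kept: int

    def __post_init__(self):
        assert self.n_input == (
            self.n_contaminant_removed + self.n_lowq_removed + self.n_kept
        ), "stats partition violated"

    @property
    def pct_contaminant(self) -> float:
        return 100.0 * self.n_contaminant_removed / self.n_input if self.n_input else 0.0

    @property
    def pct_target(self) -> float:
        return 100.0 * self.n_kept / self.n_input if self.n_input else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_reads": self.n_input,
                    "n_contaminant_removed": self.n_contaminant_removed,
                    "n_lowq_removed": self.n_lowq_removed,
                    "n_kept": self.n_kept,
                    "pct_contam": round(self.pct_contaminant, 2),
                    "pct_target": round(self.pct_target, 2),
                }
            ]
        )


def validate_alignments(df: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split a dual-alignment table into (valid, rejected-with-reason).

    Malformed records (negative MAPQ, end <= start on a mapped read) are never
    silently dropped; they come back in the second frame with a ``reason``
    column for per-record diagnostics.
    """
    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    tm = pd.to_numeric(df["target_mapq"], errors="coerce")
    cm = pd.to_numeric(df["contam_mapq"], errors="coerce")
    bad_neg = (tm.fillna(0) < 0) | (cm.fillna(0) < 0)
    reasons[bad_neg] = "negative MAPQ"

    mapped = tm.notna()
    has_coords = df["target_start"].notna() & df["target_end"].notna()
    bad_coords = mapped & has_coords & (
        pd.to_numeric(df["target_end"], errors="coerce")
        <= pd.to_numeric(df["target_start"], errors="coerce")
    )
    reasons[bad_coords & ~bad_neg] = "end <= start"
    missing_coords = mapped & ~has_coords
    reasons[missing_coords & (reasons == "")] = "mapped read without coordinates"

    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    return df[~bad].copy(), rejected


def filter_contaminant_reads(
    alignments: pd.DataFrame, mapq_floor: int = 20
) -> Tuple[pd.DataFrame, DecontamStats]:
    """Apply the contaminant-vs-target MAPQ comparison, then the MAPQ floor.

    A read (one mate) is removed as contaminant iff its contaminant-genome
    MAPQ strictly exceeds its target-genome MAPQ (absent alignments count as
    MAPQ 0; equal MAPQs keep the read).  Survivors are then removed as
    low-quality iff ``target_mapq <= mapq_floor``.  Reads unmapped in the
    target genome are dropped before statistics — they contribute no
    coordinates.

    Returns the kept alignments and a :class:`DecontamStats` whose counts
    partition the input exactly.  Filtering is idempotent.
    """
    df = alignments
    mapped = df["target_mapq"].notna()
    df = df[mapped]

    tm = df["target_mapq"].astype(float).to_numpy()
    cm = np.nan_to_num(df["contam_mapq"].astype(float).to_numpy(), nan=0.0)

    is_contam = cm > tm
    is_lowq = ~is_contam & (tm <= mapq_floor)
    keep = ~is_contam & ~is_lowq

    stats = DecontamStats(
        n_input=len(df),
        n_contaminant_removed=int(is_contam.sum()),
        n_lowq_removed=int(is_lowq.sum()),
        n_kept=int(keep.sum()),
    )
    return df[keep].copy(), stats


# ---------------------------------------------------------------------------
# IO


def read_alignments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV missing columns: {missing}")
    return df


def write_alignments_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TSV_COLUMNS)


def read_dual_sam(target_sam, contam_sam) -> pd.DataFrame:
    """Join two SAM/BAM files on (read name, mate) into a dual-alignment table.

    Secondary and supplementary records are ignored; for each (read, mate) the
    primary alignment's MAPQ is used.  Reads present only in the contaminant
    file appear with NaN target fields (and are dropped by the filter).
    """
    import pysam

    def collect(path, want_coords):
        rows = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                    continue
                mate = 2 if rec.is_read2 else 1
                key = (rec.query_name, mate)
                if key in rows:
                    continue
                if want_coords:
                    rows[key] = (rec.mapping_quality, rec.reference_name,
                                 rec.reference_start, rec.reference_end)
                else:
                    rows[key] = rec.mapping_quality
        return rows

    target = collect(target_sam, True)
    contam = collect(contam_sam, False)
    keys = sorted(set(target) | set(contam))
    rows = []
    for read_id, mate in keys:
        t = target.get((read_id, mate))
        c = contam.get((read_id, mate))
        rows.append(
            {
                "read_id": read_id,
                "mate": mate,
                "target_mapq": t[0] if t else np.nan,
                "contam_mapq": c if c is not None else np.nan,
                "target_chrom": t[1] if t else None,
                "target_start": t[2] if t else np.nan,
                "target_end": t[3] if t else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)
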