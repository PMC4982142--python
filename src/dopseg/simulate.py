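"""Synthetic DOP-PCR chromosome-sorting experiments with known truth.

The generator emulates the statistical structure of sequencing flow-sorted,
DOP-PCR amplified chromosome DNA: amplicon loci fall as a Poisson process
whose rate is high inside the genomic regions actually present on the sorted
chromosome (default 0.5 amplicons/kbp, i.e. one per 2 kbp) and low elsewhere
(default 0.025/kbp, one per 40 kbp — whole-genome background); amplicon
lengths are a two-component normal mixture (about 100 bp and 190 bp, as seen
with tagmentation library prep); each amplicon emits a read pair; a small
fraction of reads "map better" to a contaminant genome (their alignment
records carry a higher contaminant MAPQ); planted deletions inside truth
regions and assembly gaps yield no amplicons; sequence variants are planted
only within read-covered sequence so density accounting is exactly
recoverable.  Everything is reproducible from the seed.

No nucleotide-level simulation is attempted (the pipeline consumes alignment
records, not sequences); the optional motif mode derives amplicon intervals
from inward-facing occurrences of the DOP primer's 3' anchor (ATGTGG) in a
user-supplied sequence.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals
from .decontam import TSV_COLUMNS


@dataclasses.dataclass
class SimConfig:
    chrom_lengths: Dict[str, int]
    truth_regions: List[Tuple[str, int, int]]
    target_rate: float = 0.5  # amplicons per kbp inside truth regions
    background_rate: float = 0.025  # amplicons per kbp elsewhere (1 per 40 kbp)
    length_means: Tuple[float, float] = (100.0, 190.0)
    length_sds: Tuple[float, float] = (10.0, 10.0)
    length_weights: Tuple[float, float] = (0.5, 0.5)
    contamination_fraction: float = 0.02
    lowq_fraction: float = 0.05  # reads failing the MAPQ floor
    planted_deletions: List[Tuple[str, int, int]] = dataclasses.field(default_factory=list)
    assembly_gaps: List[Tuple[str, int, int]] = dataclasses.field(default_factory=list)
    read_length: int = 150
    variant_rate_target: float = 1 / 23.0  # per covered bp, B-region-like divergence
    variant_rate_background: float = 1 / 316.0  # autosome-like
    het_fraction_target: float = 0.6
    het_fraction_background: float = 0.33
    seed: int = 0

    def validate(self) -> None:
        if self.target_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if abs(sum(self.length_weights) - 1.0) > 1e-9:
            raise ValueError("length mixture weights must sum to 1")
        for chrom, s, e in self.truth_regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"truth region on unknown chromosome {chrom}")
            if s < 0 or e > self.chrom_lengths[chrom] or e <= s:
                raise ValueError(f"truth region {chrom}:{s}-{e} outside chromosome")
        for chrom, s, e in self.planted_deletions:
            inside = any(
                c == chrom and s >= rs and e <= re for c, rs, re in self.truth_regions
            )
            if not inside:
                raise ValueError(f"deletion {chrom}:{s}-{e} not inside a truth region")


@dataclasses.dataclass
class SimResult:
    alignments: pd.DataFrame  # DualAlignment table
    truth_regions: pd.DataFrame  # chrom, start, end
    truth_deletions: pd.DataFrame
    truth_variants: pd.DataFrame  # callset frame
    amplicons: pd.DataFrame  # chrom, start, end (merged truth loci)
    config: SimConfig


def _rate_intervals(cfg: SimConfig) -> List[Tuple[str, int, int, float]]:
    """Disjoint (chrom, start, end, rate-per-bp) pieces covering the genome."""
    out = []
    regions_by_chrom: Dict[str, list] = {}
    for c, s, e in cfg.truth_regions:
        regions_by_chrom.setdefault(c, []).append((s, e))
    dels_by_chrom: Dict[str, list] = {}
    for c, s, e in cfg.planted_deletions:
        dels_by_chrom.setdefault(c, []).append((s, e))
    gaps_by_chrom: Dict[str, list] = {}
    for c, s, e in cfg.assembly_gaps:
        gaps_by_chrom.setdefault(c, []).append((s, e))

    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        regions = _intervals.merge(regions_by_chrom.get(chrom, []))
        dead = _intervals.merge(
            dels_by_chrom.get(chrom, []) + gaps_by_chrom.get(chrom, [])
        ) if (chrom in dels_by_chrom or chrom in gaps_by_chrom) else np.empty((0, 2), np.int64)
        target_live = _intervals.subtract(regions, dead) if len(regions) else regions
        bg = _intervals.subtract([(0, length)], regions)
        bg_live = _intervals.subtract(bg, dead) if len(bg) else bg
        for s, e in target_live:
            out.append((chrom, int(s), int(e), cfg.target_rate / 1000.0))
        for s, e in bg_live:
            out.append((chrom, int(s), int(e), cfg.background_rate / 1000.0))
    return out


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Draw a full synthetic experiment; byte-identical given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    amp_rows = []
    for chrom, s, e, rate in _rate_intervals(cfg):
        if rate <= 0:
            continue
        n = rng.poisson(rate * (e - s))
        if n == 0:
            continue
        starts = np.sort(rng.integers(s, e, size=n))
        comp = rng.random(n) < cfg.length_weights[0]
        lens = np.where(
            comp,
            rng.normal(cfg.length_means[0], cfg.length_sds[0], n),
            rng.normal(cfg.length_means[1], cfg.length_sds[1], n),
        )
        lens = np.maximum(np.round(lens).astype(np.int64), 30)
        ends = np.minimum(starts + lens, cfg.chrom_lengths[chrom])
        for a, b in zip(starts, ends):
            amp_rows.append((chrom, int(a), int(b)))

    # each amplicon emits one read pair: mates cover its two ends
    aln_rows = []
    rid = 0
    for chrom, a, b in amp_rows:
        rl = min(cfg.read_length, b - a)
        for mate, (s, e) in enumerate(((a, a + rl), (b - rl, b)), start=1):
            u = rng.random()
            if u < cfg.contamination_fraction:
                tm = int(rng.integers(0, 31))
                cmq = tm + int(rng.integers(5, 31))
            elif u < cfg.contamination_fraction + cfg.lowq_fraction:
                tm = int(rng.integers(0, 21))  # fails MAPQ floor
                cmq = 0
            else:
                tm = int(rng.integers(25, 61))
                cmq = int(rng.integers(0, min(tm, 20) + 1))
            aln_rows.append(
                {
                    "read_id": f"sim{rid:08d}",
                    "mate": mate,
                    "target_mapq": tm,
                    "contam_mapq": cmq,
                    "target_chrom": chrom,
                    "target_start": s,
                    "target_end": e,
                }
            )
        rid += 1
    alignments = pd.DataFrame(aln_rows, columns=TSV_COLUMNS)

    truth_regions = pd.DataFrame(
        sorted(cfg.truth_regions), columns=["chrom", "start", "end"]
    )
    truth_deletions = pd.DataFrame(
        sorted(cfg.planted_deletions), columns=["chrom", "start", "end"]
    )

    # merged amplicon loci = truth DOP-positions (clean reads only would
    # recover these up to contaminant/low-quality losses)
    amp_by_chrom: Dict[str, list] = {}
    for chrom, a, b in amp_rows:
        amp_by_chrom.setdefault(chrom, []).append((a, b))
    amp_merged = [
        (chrom, int(s), int(e))
        for chrom in sorted(amp_by_chrom)
        for s, e in _intervals.merge(amp_by_chrom[chrom])
    ]
    amplicons = pd.DataFrame(amp_merged, columns=["chrom", "start", "end"])

    truth_variants = _plant_variants(cfg, amplicons, rng)

    return SimResult(
        alignments=alignments,
        truth_regions=truth_regions,
        truth_deletions=truth_deletions,
        truth_variants=truth_variants,
        amplicons=amplicons,
        config=cfg,
    )


_BASES = np.array(list("ACGT"))


def _plant_variants(cfg: SimConfig, amplicons: pd.DataFrame, rng) -> pd.DataFrame:
    """Place SNVs only within covered (amplicon) intervals, per compartment."""
    regions_by_chrom: Dict[str, list] = {}
    for c, s, e in cfg.truth_regions:
        regions_by_chrom.setdefault(c, []).append((s, e))

    rows = []
    for chrom, grp in amplicons.groupby("chrom"):
        cov = np.column_stack(
            [grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)]
        )
        regions = _intervals.merge(regions_by_chrom.get(str(chrom), [])) if str(
            chrom
        ) in regions_by_chrom else np.empty((0, 2), np.int64)
        in_target = _intervals.intersect(cov, regions) if len(regions) else np.empty((0, 2), np.int64)
        in_bg = _intervals.subtract(cov, regions) if len(regions) else cov
        for ivs, rate, het_frac in (
            (in_target, cfg.variant_rate_target, cfg.het_fraction_target),
            (in_bg, cfg.variant_rate_background, cfg.het_fraction_background),
        ):
            for s, e in ivs:
                n = rng.binomial(e - s, min(rate, 1.0))
                if n == 0:
                    continue
                pos0 = np.sort(rng.choice(np.arange(s, e), size=n, replace=False))
                ref_i = rng.integers(0, 4, size=n)
                alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
                het = rng.random(n) < het_frac
                for p, r, a, h in zip(pos0, ref_i, alt_i, het):
                    rows.append(
                        {
                            "chrom": str(chrom),
                            "pos": int(p) + 1,
                            "ref": _BASES[r],
                            "alt": _BASES[a],
                            "zygosity": "het" if h else "hom",
                            "depth": int(rng.integers(2, 30)),
                        }
                    )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "zygosity", "depth"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif-driven amplicons


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def simulate_motif_amplicons(
    sequence: str,
    primer_3prime: str = "ATGTGG",
    min_len: int = 50,
    max_len: int = 1500,
) -> List[Tuple[int, int]]:
    """Amplicon intervals between inward-facing primer-anchor occurrences.

    A forward anchor (the motif on the + strand) pairs with the nearest
    downstream reverse-complement occurrence such that the spanned length is
    within [min_len, max_len]; each forward anchor yields at most one
    amplicon.  Deterministic given the sequence.
    """
    seq = str(sequence).upper()
    fwd = primer_3prime.upper()
    rev = _revcomp(fwd)

    def find_all(pat):
        out, i = [], seq.find(pat)
        while i != -1:
            out.append(i)
            i = seq.find(pat, i + 1)
        return out

    fwd_pos = find_all(fwd)
    rev_pos = find_all(rev)
    rev_ends = np.array([p + len(rev) for p in rev_pos], dtype=np.int64)

    amplicons = []
    for f in fwd_pos:
        # nearest downstream reverse anchor whose end keeps length in range
        candidates = rev_ends[(rev_ends - f >= min_len) & (rev_ends - f <= max_len)]
        candidates = candidates[candidates > f]
        if len(candidates):
            amplicons.append((f, int(candidates.min())))
    return amplicons


# ---------------------------------------------------------------------------
# study-shaped default configurations (desk scale)


def roe_like_config(seed: int = 0) -> SimConfig:
    """Two truth regions (1.94 Mbp + 41 kbp) with two internal deletions
    (420 kbp and 140 kbp), on a small 4-chromosome genome."""
    return SimConfig(
        chrom_lengths={"chr3": 8_000_000, "chr28": 3_000_000, "chr10": 5_000_000, "chr11": 5_000_000},
        truth_regions=[
            ("chr3", 3_000_000, 4_938_559),
            ("chr28", 1_200_000, 1_241_120),
        ],
        planted_deletions=[
            ("chr3", 3_330_000, 3_750_000),
            ("chr3", 4_130_000, 4_270_000),
        ],
        assembly_gaps=[("chr3", 4_150_000, 4_200_000), ("chr10", 2_000_000, 2_100_000)],
        seed=seed,
    )


# region sizes mirror the 26 detected homology regions (23 kbp - 1.83 Mbp)
_BROCKET_SIZES = [
    258_267, 53_305, 95_705, 183_947, 54_723, 1_827_377, 76_596, 220_170,
    539_858, 74_715, 268_816, 704_663, 769_432, 553_800, 229_073, 237_119,
    154_813, 358_267, 90_136, 22_826, 191_211, 307_342, 286_848, 64_332,
    774_509, 913_860,
]


def brocket_like_config(seed: int = 0) -> SimConfig:
    """26 truth regions with the brocket-deer size spectrum, two per chromosome."""
    chrom_lengths: Dict[str, int] = {}
    regions: List[Tuple[str, int, int]] = []
    pad = 700_000
    for i in range(13):
        chrom = f"chr{i + 1:02d}"
        sizes = _BROCKET_SIZES[2 * i : 2 * i + 2]
        cur = pad
        for sz in sizes:
            regions.append((chrom, cur, cur + sz))
            cur += sz + pad
        chrom_lengths[chrom] = cur
    return SimConfig(chrom_lengths=chrom_lengths, truth_regions=regions, seed=seed)


# ---------------------------------------------------------------------------
# plain-text artifacts


def write_truth_bed(df: pd.DataFrame, path) -> None:
    df.sort_values(["chrom", "start"]).to_csv(
        path, sep="\t", header=False, index=False, columns=["chrom", "start", "end"]
    )


def config_echo(cfg: SimConfig) -> str:
    """Key-value echo of the configuration, for run provenance."""
    buf = io.StringIO()
    for field in dataclasses.fields(cfg):
        buf.write(f"{field.name}\t{getattr(cfg, field.name)!r}\n")
    return buf.getvalue()
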