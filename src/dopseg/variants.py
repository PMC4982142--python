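"""Variant accounting on called target regions.

Given a VCF callset from the chromosome-specific reads, this module performs
the bookkeeping behind a per-feature variation table: subtraction of a second
callset (e.g. a close relative's derived positions, to strip species-level
divergence), sizes of read-covered sequence per gene-feature class, variant
density (bp per variant, all and heterozygous-only), het/hom ratio, novelty
against a known-variant set under depth filters, and a lightweight effect
classifier (intergenic / intron / UTR / synonymous / non-synonymous).

Callsets are pandas DataFrames with columns ``chrom, pos (1-based), ref,
alt, zygosity ('het'|'hom'), depth`` and optionally ``effect``.  Matching
between callsets is exact on (chrom, pos, ref, alt) after left-trimming
shared allele prefixes.

Feature classes overlap in real annotations; reporting assigns one class per
bp / variant with precedence coding > UTR > intron > intergenic.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals

EFFECT_CATEGORIES = ["intergenic", "intron", "utr5", "utr3", "coding_syn", "coding_nonsyn"]
FEATURE_CLASSES = ["intergenic", "intron", "utr5", "utr3", "coding"]

CALLSET_COLUMNS = ["chrom", "pos", "ref", "alt", "zygosity", "depth"]


# ---------------------------------------------------------------------------
# gene models


@dataclasses.dataclass
class GeneModel:
    """Transcript extent with exon blocks and a CDS span (BED12 semantics)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]]
    cds_start: int  # thickStart; == cds_end means non-coding
    cds_end: int


def read_bed12(path) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                thick_s, thick_e = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            else:
                thick_s, thick_e = start, end
                exons = [(start, end)]
            genes.append(GeneModel(name, chrom, start, end, strand, exons, thick_s, thick_e))
    return genes


def read_gff3_genes(path) -> List[GeneModel]:
    """Minimal GFF3 reader: gene extent from ``gene`` rows, exons/CDS by Parent chain."""
    genes: Dict[str, GeneModel] = {}
    parent_of: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            start, end = int(start) - 1, int(end)  # GFF is 1-based inclusive
            kv = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            fid = kv.get("ID", "")
            parent = kv.get("Parent", "")
            if ftype == "gene":
                gid = kv.get("Name", fid) or fid
                genes[fid or gid] = GeneModel(gid, chrom, start, end, strand, [], end, end)
            elif ftype in ("mRNA", "transcript"):
                parent_of[fid] = parent
            elif ftype in ("exon", "CDS"):
                root = parent
                while root in parent_of:
                    root = parent_of[root]
                g = genes.get(root)
                if g is None:
                    continue
                if ftype == "exon":
                    g.exons.append((start, end))
                else:
                    g.cds_start = min(g.cds_start, start)
                    g.cds_end = max(g.cds_end if g.cds_end > g.cds_start else start, end)
    out = []
    for g in genes.values():
        if not g.exons:
            g.exons = [(g.start, g.end)]
        if g.cds_start >= g.cds_end:
            g.cds_start = g.cds_end = g.end  # non-coding
        g.exons.sort()
        out.append(g)
    return out


def gene_models_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in genes
        ],
        columns=["gene_id", "chrom", "start", "end"],
    )


# ---------------------------------------------------------------------------
# feature maps


def _feature_intervals(
    genes: Sequence[GeneModel],
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-chromosome interval sets for coding / utr5 / utr3 / intron.

    Overlaps between classes are resolved by precedence
    coding > UTR > intron; intergenic is everything else and is computed by
    the callers as a complement.
    """
    per_class: Dict[str, Dict[str, list]] = {
        c: {} for c in ("coding", "utr5", "utr3", "intron")
    }
    for g in genes:
        exons = _intervals.merge(g.exons)
        span = [(g.start, g.end)]
        introns = _intervals.subtract(span, exons)
        coding = (
            _intervals.intersect(exons, [(g.cds_start, g.cds_end)])
            if g.cds_end > g.cds_start
            else np.empty((0, 2), dtype=np.int64)
        )
        utr_left = _intervals.intersect(exons, [(g.start, g.cds_start)])
        utr_right = _intervals.intersect(exons, [(g.cds_end, g.end)])
        if g.strand == "-":
            utr5, utr3 = utr_right, utr_left
        else:
            utr5, utr3 = utr_left, utr_right
        for cls, ivs in (
            ("coding", coding),
            ("utr5", utr5),
            ("utr3", utr3),
            ("intron", introns),
        ):
            if len(ivs):
                per_class[cls].setdefault(g.chrom, []).extend(map(tuple, ivs))

    out: Dict[str, Dict[str, np.ndarray]] = {c: {} for c in per_class}
    chroms = set()
    for c in per_class:
        chroms |= set(per_class[c])
    for chrom in chroms:
        higher: Optional[np.ndarray] = None
        for cls in ("coding", "utr5", "utr3", "intron"):  # precedence order
            ivs = _intervals.merge(per_class[cls].get(chrom, []))
            if higher is not None and len(ivs):
                ivs = _intervals.subtract(ivs, higher)
            if len(ivs):
                out[cls][chrom] = ivs
                higher = ivs if higher is None else _intervals.merge(
                    np.vstack([higher, ivs])
                )
            elif higher is None:
                higher = np.empty((0, 2), dtype=np.int64)
    return out


@dataclasses.dataclass
class CoveredFeatureSizes:
    """bp of read-covered sequence per feature class (Table-style 'A' panel)."""

    total: int
    intergenic: int
    intron: int
    utr5: int
    utr3: int
    coding: int

    def as_dict(self) -> Dict[str, int]:
        return dataclasses.asdict(self)


def covered_feature_sizes(
    covered_intervals: Sequence[Tuple[str, int, int]],
    genes: Sequence[GeneModel],
) -> CoveredFeatureSizes:
    """Intersect read-covered intervals with the gene-feature map."""
    by_chrom: Dict[str, list] = {}
    for chrom, s, e in covered_intervals:
        by_chrom.setdefault(str(chrom), []).append((int(s), int(e)))
    fmap = _feature_intervals(genes)
    sizes = {c: 0 for c in FEATURE_CLASSES}
    total = 0
    for chrom, ivs in by_chrom.items():
        cov = _intervals.merge(ivs)
        total += _intervals.total_length(cov)
        for cls in ("coding", "utr5", "utr3", "intron"):
            f_ivs = fmap[cls].get(chrom)
            if f_ivs is not None:
                sizes[cls] += _intervals.intersect_length(cov, f_ivs)
    sizes["intergenic"] = total - sizes["coding"] - sizes["utr5"] - sizes["utr3"] - sizes["intron"]
    return CoveredFeatureSizes(total=total, **sizes)


# ---------------------------------------------------------------------------
# callset algebra


def _norm_key(chrom, pos, ref, alt) -> Tuple[str, int, str, str]:
    """Exact matching key; shared allele prefixes are left-trimmed."""
    ref, alt = str(ref), str(alt)
    pos = int(pos)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return (str(chrom), pos, ref, alt)


def _keys(df: pd.DataFrame) -> pd.Index:
    return pd.Index(
        [_norm_key(c, p, r, a) for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])]
    )


def subtract_callsets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Variants of A absent from B (exact chrom/pos/ref/alt match).

    Raises if the two callsets share no contig names (coordinate-system
    mismatch), listing the offending contigs.
    """
    if len(a) and len(b):
        ca, cb = set(map(str, a["chrom"])), set(map(str, b["chrom"]))
        if not (ca & cb):
            raise ValueError(
                f"callsets share no contigs: A has {sorted(ca)[:5]}, B has {sorted(cb)[:5]}"
            )
    if len(a) == 0:
        return a.copy()
    mask = ~_keys(a).isin(set(_keys(b)))
    return a[np.asarray(mask)].copy()


def het_hom_ratio(variants: pd.DataFrame) -> Optional[float]:
    """n_het / n_hom; None (undefined) when there are no homozygous calls."""
    n_het = int((variants["zygosity"] == "het").sum())
    n_hom = int((variants["zygosity"] == "hom").sum())
    if n_hom == 0:
        return None
    return n_het / n_hom


def novelty_stats(
    variants: pd.DataFrame, known: pd.DataFrame, min_depth: int = 0
) -> Dict[str, float]:
    """Fraction of variants absent from a known-variant set, after a depth filter."""
    sub = variants[variants["depth"] >= min_depth] if min_depth > 0 else variants
    n_total = len(sub)
    if n_total == 0:
        return {"n_total": 0, "n_novel": 0, "pct_novel": float("nan")}
    novel = ~_keys(sub).isin(set(_keys(known))) if len(known) else np.ones(n_total, bool)
    n_novel = int(np.asarray(novel).sum())
    return {
        "n_total": n_total,
        "n_novel": n_novel,
        "pct_novel": 100.0 * n_novel / n_total,
    }


# ---------------------------------------------------------------------------
# density table


@dataclasses.dataclass
class DensityTable:
    """bp-per-variant densities (integer-rounded), all and het-only.

    ``None`` marks a category with zero variants (printed as '-'), never 0.
    """

    density_all: Dict[str, Optional[int]]
    density_het: Dict[str, Optional[int]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in ["total"] + FEATURE_CLASSES:
            rows.append(
                {
                    "category": cat,
                    "density_all": self.density_all.get(cat),
                    "density_het": self.density_het.get(cat),
                }
            )
        return pd.DataFrame(rows)


def variant_density_from_counts(
    sizes_bp: Dict[str, int],
    counts_all: Dict[str, int],
    counts_het: Dict[str, int],
) -> DensityTable:
    """Density = round(category bp / category variant count); the core rule.

    Categories with zero variants are undefined (None).  ``sizes_bp`` uses
    feature-class keys plus ``total``; counts may carry extra keys (ignored).
    """

    def dens(counts):
        out = {}
        for cat, bp in sizes_bp.items():
            n = counts.get(cat, 0)
            out[cat] = int(round(bp / n)) if n > 0 else None
        return out

    return DensityTable(density_all=dens(counts_all), density_het=dens(counts_het))


def variant_density(sizes: CoveredFeatureSizes, variants: pd.DataFrame) -> DensityTable:
    """Count a callset per effect category and derive the density table.

    Effects must be assigned (see :func:`classify_effect`); the two coding
    effect categories pool into the 'coding' feature class.
    """
    if sizes.total <= 0:
        raise ValueError("covered total must be positive")
    size_map = {"total": sizes.total, **{c: getattr(sizes, c) for c in FEATURE_CLASSES}}

    def count(sub: pd.DataFrame) -> Dict[str, int]:
        eff = sub["effect"] if "effect" in sub else pd.Series(index=sub.index, dtype=object)
        c = {
            "intergenic": int((eff == "intergenic").sum()),
            "intron": int((eff == "intron").sum()),
            "utr5": int((eff == "utr5").sum()),
            "utr3": int((eff == "utr3").sum()),
            "coding": int(eff.isin(["coding_syn", "coding_nonsyn"]).sum()),
        }
        c["total"] = len(sub)
        return c

    return variant_density_from_counts(
        size_map, count(variants), count(variants[variants["zygosity"] == "het"])
    )


# ---------------------------------------------------------------------------
# effect classification


def classify_effect(
    variant: pd.Series | dict,
    genes: Sequence[GeneModel],
    reference,
) -> str:
    """Assign one effect category to a variant (precedence coding > UTR > intron).

    ``reference`` is a mapping chrom -> sequence (pyfaidx.Fasta works).  For a
    CDS SNV the affected codon is translated with and without the alternate
    allele (standard genetic code); any CDS indel is non-synonymous
    (frameshift or inframe).  A ref allele disagreeing with the reference
    sequence raises.
    """
    from Bio.Seq import Seq

    chrom = str(variant["chrom"])
    pos0 = int(variant["pos"]) - 1  # VCF is 1-based
    ref, alt = str(variant["ref"]), str(variant["alt"])

    seq = reference[chrom]
    ref_slice = str(seq[pos0 : pos0 + len(ref)]).upper()
    if ref_slice != ref.upper():
        raise ValueError(
            f"{chrom}:{pos0 + 1} ref allele {ref!r} disagrees with reference {ref_slice!r}"
        )

    var_iv = (pos0, pos0 + max(len(ref), 1))
    best = "intergenic"
    rank = {"intergenic": 0, "intron": 1, "utr3": 2, "utr5": 2, "coding_syn": 3, "coding_nonsyn": 3}
    for g in genes:
        if g.chrom != chrom or var_iv[1] <= g.start or var_iv[0] >= g.end:
            continue
        cat = _effect_in_gene(g, pos0, ref, alt, seq, Seq)
        if rank[cat] > rank[best]:
            best = cat
    return best


def _effect_in_gene(g: GeneModel, pos0: int, ref: str, alt: str, seq, Seq) -> str:
    in_exon = any(s <= pos0 < e for s, e in g.exons)
    in_cds = g.cds_start <= pos0 < g.cds_end and in_exon
    if in_cds:
        if len(ref) != len(alt):
            return "coding_nonsyn"  # frameshift or inframe indel
        if len(ref) == 1:
            return _snv_coding_effect(g, pos0, alt, seq, Seq)
        return "coding_nonsyn"  # MNV: treated as disruptive
    if in_exon:
        if pos0 < g.cds_start:
            side = "utr5" if g.strand == "+" else "utr3"
        else:
            side = "utr3" if g.strand == "+" else "utr5"
        return side
    return "intron"


def _snv_coding_effect(g: GeneModel, pos0: int, alt: str, seq, Seq) -> str:
    # CDS coordinate of pos0 in transcription order
    cds_exons = []
    for s, e in sorted(g.exons):
        cs, ce = max(s, g.cds_start), min(e, g.cds_end)
        if cs < ce:
            cds_exons.append((cs, ce))
    offs = 0
    cds_pos = None
    for s, e in cds_exons:
        if s <= pos0 < e:
            cds_pos = offs + (pos0 - s)
            break
        offs += e - s
    if cds_pos is None:
        return "intron"
    cds_seq = "".join(str(seq[s:e]).upper() for s, e in cds_exons)
    if g.strand == "-":
        cds_pos = len(cds_seq) - 1 - cds_pos
        cds_seq = str(Seq(cds_seq).reverse_complement())
        alt_base = str(Seq(alt.upper()).reverse_complement())
    else:
        alt_base = alt.upper()
    codon_i = cds_pos // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "coding_nonsyn"  # truncated terminal codon: treat as disruptive
    mutated = codon[: cds_pos % 3] + alt_base + codon[cds_pos % 3 + 1 :]
    same = str(Seq(codon).translate()) == str(Seq(mutated).translate())
    return "coding_syn" if same else "coding_nonsyn"


def classify_callset(
    variants: pd.DataFrame, genes: Sequence[GeneModel], reference
) -> pd.DataFrame:
    out = variants.copy()
    out["effect"] = [
        classify_effect(row, genes, reference) for _, row in variants.iterrows()
    ]
    return out


# ---------------------------------------------------------------------------
# VCF IO (pysam)


def read_vcf(path) -> pd.DataFrame:
    """Load a VCF into the callset frame; zygosity from the first sample's GT.

    Records without samples fall back to ``hom``; depth from FORMAT DP, then
    INFO DP, else 0.  Multi-allelic records expand to one row per ALT.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gt = None
            depth = rec.info.get("DP", 0)
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
                depth = sample.get("DP") or depth or 0
            for alt in rec.alts or ():
                if gt and None not in gt:
                    zyg = "het" if len(set(gt)) > 1 else "hom"
                else:
                    zyg = "hom"
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "zygosity": zyg,
                        "depth": int(depth or 0),
                    }
                )
    return pd.DataFrame(rows, columns=CALLSET_COLUMNS)


def write_vcf(df: pd.DataFrame, path, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = contig_lengths or {
        str(c): 2**29 for c in pd.unique(df["chrom"].astype(str))
    }
    for name, ln in contigs.items():
        header.contigs.add(str(name), length=int(ln))
    header.add_sample("sample1")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in df.sort_values(["chrom", "pos"]).iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.info["DP"] = int(row.get("depth", 0))
            rec.samples["sample1"]["GT"] = (0, 1) if row["zygosity"] == "het" else (1, 1)
            out.write(rec)
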