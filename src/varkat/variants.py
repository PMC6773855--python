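"""Variant containers and VCF/BED/TSV input-output.

In-memory model
---------------
A :class:`VariantRecord` is one decomposed site+allele (exactly one ALT) with
per-sample :class:`GenotypeCall` objects, per-site statistics
(:class:`SiteStats`, the GATK-style INFO annotations used for PASS flagging)
and annotations: gene, effect category, signed distance to the nearest
intron-exon boundary, and population allele frequencies keyed by source.

Coordinate conventions
----------------------
Positions are 1-based (VCF). ``boundary_offset`` is signed: negative values
are intronic (-1 = first intronic base past the boundary), positive values
exonic (+1 = the boundary-adjacent exonic base); 0 is not a valid offset.

VCF dialect
-----------
Files are VCF 4.2. FORMAT carries GT, DP, GQ, VF (variant read fraction) and
SB (strand bias); indel records additionally carry R8 (homopolymer-adjacent
indel metric). INFO carries the site statistics plus GENE, EFFECT and BOFF
annotations. Population AFs travel in a separate TSV
(chrom, pos, ref, alt, source, af).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

EFFECT_CATEGORIES = (
    "LoF",
    "nonsynonymous",
    "synonymous",
    "inframe",
    "splice_region",
    "noncoding",
)


@dataclass
class GenotypeCall:
    """One sample's call at one site, with the quality fields the panel
    filters consume."""

    sample: str
    alleles: tuple[Optional[int], Optional[int]]  # 0=ref, 1=alt, None=missing
    DP: Optional[int] = None
    GQ: Optional[float] = None
    GQX: Optional[float] = None  # min(GQ, site QUAL proxy)
    variant_read_fraction: Optional[float] = None
    SB: Optional[float] = None
    R8: Optional[float] = None  # indel-context metric, absent for SNVs

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.alleles[0] != self.alleles[1]

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles == (1, 1)

    @property
    def n_alt(self) -> int:
        return sum(1 for a in self.alleles if a == 1)


@dataclass
class SiteStats:
    """GATK-style per-site statistics used for PASS flagging."""

    QD: Optional[float] = None
    MQ: Optional[float] = None
    FS: Optional[float] = None
    HaplotypeScore: Optional[float] = None
    MQRankSum: Optional[float] = None
    ReadPosRankSum: Optional[float] = None
    snp_cluster_count: Optional[int] = None
    variant_class: str = "snv"  # "snv" | "indel"


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    qual: Optional[float] = None
    filter: Optional[str] = None
    stats: SiteStats = field(default_factory=SiteStats)
    gene: Optional[str] = None
    effect: Optional[str] = None
    boundary_offset: Optional[int] = None
    population_afs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multiallelic record at {self.chrom}:{self.pos}; decompose upstream"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def call(self, sample: str) -> GenotypeCall:
        return self.calls[sample]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_FLOATS = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">',
    '##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype score">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##INFO=<ID=SNPCLUSTER,Number=1,Type=Integer,Description="SNVs within 35 bp window">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">',
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect category">',
    '##INFO=<ID=BOFF,Number=1,Type=Integer,Description="Signed distance to nearest intron-exon boundary (negative=intronic)">',
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FILTER=<ID=FAIL,Description="Site-level criterion tripped">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=VF,Number=1,Type=Float,Description="Variant read fraction">',
    '##FORMAT=<ID=SB,Number=1,Type=Float,Description="Strand bias score">',
    '##FORMAT=<ID=R8,Number=1,Type=Float,Description="Homopolymer-adjacent indel metric">',
]


def _fmt(x, nd=2) -> str:
    if x is None:
        return "."
    if isinstance(x, float):
        return f"{x:.{nd}f}".rstrip("0").rstrip(".") or "0"
    return str(x)


def write_vcf(records: Iterable[VariantRecord], samples: list[str], path: str | Path) -> None:
    """Write records as uncompressed VCF 4.2 in the package dialect."""
    records = list(records)
    lines = list(VCF_HEADER_LINES)
    lines += [
        f"##contig=<ID={c}>" for c in dict.fromkeys(r.chrom for r in records)
    ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        info_parts = []
        s = rec.stats
        for k in _INFO_FLOATS:
            v = getattr(s, k)
            if v is not None:
                info_parts.append(f"{k}={_fmt(v)}")
        if s.snp_cluster_count is not None:
            info_parts.append(f"SNPCLUSTER={s.snp_cluster_count}")
        if rec.gene is not None:
            info_parts.append(f"GENE={rec.gene}")
        if rec.effect is not None:
            info_parts.append(f"EFFECT={rec.effect}")
        if rec.boundary_offset is not None:
            info_parts.append(f"BOFF={rec.boundary_offset}")
        info = ";".join(info_parts) if info_parts else "."
        sample_cols = []
        for sm in samples:
            c = rec.calls.get(sm)
            if c is None or c.is_missing:
                gt = "./."
            else:
                gt = f"{c.alleles[0]}/{c.alleles[1]}"
            if c is None:
                sample_cols.append("./.:.:.:.:.:.")
                continue
            sample_cols.append(
                ":".join(
                    [
                        gt,
                        _fmt(c.DP),
                        _fmt(None if c.GQ is None else int(round(c.GQ))),
                        _fmt(c.variant_read_fraction, nd=3),
                        _fmt(c.SB),
                        _fmt(c.R8),
                    ]
                )
            )
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    ".",
                    rec.ref,
                    rec.alt,
                    _fmt(rec.qual),
                    rec.filter or ".",
                    info,
                    "GT:DP:GQ:VF:SB:R8",
                ]
                + sample_cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF 4.2 file into VariantRecords via cyvcf2.

    Multiallelic rows are rejected (the pipeline requires decomposed input).
    GQX is derived at read time as min(GQ, site QUAL).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS}; decompose upstream"
            )
        stats = SiteStats(
            QD=v.INFO.get("QD"),
            MQ=v.INFO.get("MQ"),
            FS=v.INFO.get("FS"),
            HaplotypeScore=v.INFO.get("HaplotypeScore"),
            MQRankSum=v.INFO.get("MQRankSum"),
            ReadPosRankSum=v.INFO.get("ReadPosRankSum"),
            snp_cluster_count=v.INFO.get("SNPCLUSTER"),
            variant_class="indel" if v.is_indel else "snv",
        )
        qual = v.QUAL
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dps = v.format("DP")
        gqs = v.format("GQ")
        vfs = v.format("VF")
        sbs = v.format("SB")
        r8s = v.format("R8")
        calls = {}
        for i, sm in enumerate(samples):
            a0, a1 = gts[i][0], gts[i][1]
            alleles = (None if a0 < 0 else a0, None if a1 < 0 else a1)
            gq = None if gqs is None or gqs[i][0] < 0 else float(gqs[i][0])
            gqx = None
            if gq is not None:
                gqx = gq if qual is None else min(gq, float(qual))
            def _val(arr):
                if arr is None:
                    return None
                x = float(arr[i][0])
                return None if math.isnan(x) else x
            dp = None if dps is None or dps[i][0] < 0 else int(dps[i][0])
            calls[sm] = GenotypeCall(
                sample=sm,
                alleles=alleles,
                DP=dp,
                GQ=gq,
                GQX=gqx,
                variant_read_fraction=_val(vfs),
                SB=_val(sbs),
                R8=_val(r8s),
            )
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                calls=calls,
                qual=qual,
                filter="PASS" if v.FILTER is None else v.FILTER,
                stats=stats,
                gene=v.INFO.get("GENE"),
                effect=v.INFO.get("EFFECT"),
                boundary_offset=v.INFO.get("BOFF"),
            )
        )
    return records, samples


# ---------------------------------------------------------------------------
# Allele-frequency table / BED
# ---------------------------------------------------------------------------

def read_af_table(path: str | Path) -> dict[tuple[str, int, str, str], dict[str, float]]:
    """Read a TSV (chrom, pos, ref, alt, source, af) into a key->source->AF map."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[tuple[str, int, str, str], dict[str, float]] = {}
    for row in df.itertuples(index=False):
        af = float(row.af)
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1]")
        out.setdefault((row.chrom, int(row.pos), row.ref, row.alt), {})[row.source] = af
    return out


def write_af_table(afs: dict[tuple[str, int, str, str], dict[str, float]], path: str | Path) -> None:
    rows = []
    for (chrom, pos, ref, alt), srcs in afs.items():
        for source, af in srcs.items():
            rows.append((chrom, pos, ref, alt, source, af))
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "source", "af"]).to_csv(
        path, sep="\t", index=False
    )


def annotate_population_afs(records: Iterable[VariantRecord], afs) -> None:
    """Attach population AFs in place; records absent from the table stay empty."""
    for rec in records:
        rec.population_afs = dict(afs.get(rec.key, {}))


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) intervals as (chrom, start, end)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split()[:3]
        start, end = int(start), int(end)
        if end < start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end} (end < start)")
        out.append((chrom, start, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{c}\t{s}\t{e}" for c, s, e in intervals) + "\n"
    )
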