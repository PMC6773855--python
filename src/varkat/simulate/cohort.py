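"""Synthetic two-family cohort generator.

Emulates the discovery setting: two nominally unrelated nuclear families
segregating the same recessive founder allele. The generator plants

* one causal splice-donor variant, homozygous-alternate in every affected
  child and heterozygous in every parent of both families;
* a shared homozygous block around it (a founder haplotype): every site
  inside the block is homozygous for identical alleles in the affected
  individuals of both families, with common population frequencies so the
  block is visible to run-of-homozygosity scanning but removed by the
  rare-variant frequency filter;
* background variants with a Beta-shaped rare-skewed allele-frequency
  spectrum, Hardy-Weinberg founder genotypes and Mendelian transmission;
* per-call quality fields (DP, GQ, variant read fraction, SB, R8) and
  per-site GATK-style statistics, with a configurable fraction of records
  deliberately failing each filter threshold so filters are exercised in
  both directions;
* optionally planted de-novo events (default none).

All randomness comes from one ``numpy.random.Generator`` seeded from the
spec; identical spec + seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ..pedigree import Individual, Pedigree, write_ped
from ..variants import (
    GenotypeCall,
    SiteStats,
    VariantRecord,
    write_af_table,
    write_bed,
    write_vcf,
)

EFFECT_WEIGHTS = {
    "synonymous": 0.33,
    "nonsynonymous": 0.40,
    "noncoding": 0.15,
    "inframe": 0.04,
    "LoF": 0.03,
    "splice_region": 0.05,
}

AF_SOURCES = ("gnomAD", "ExAC", "1000G")


@dataclass
class FamilyStructure:
    n_parents: int = 2
    n_affected: int = 2
    n_unaffected: int = 0

    def __post_init__(self) -> None:
        if self.n_affected >= 1 and self.n_parents != 2:
            raise ValueError(
                "affected children require two genotyped parents in the trio design"
            )


@dataclass
class GenotypeQualityModel:
    """Means/dispersions of the per-call quality fields, plus the fraction
    of background records whose proband call deliberately fails each panel
    filter threshold."""

    depth_mean: float = 40.0
    depth_shape: float = 10.0  # gamma shape of the per-call depth mixture
    gq_high: int = 99
    gq_low_rate: float = 0.01  # chance of a low-GQ call (uniform 10..98)
    het_fraction_conc: float = 60.0  # Beta concentration of het read fraction
    sb_mean: float = -30.0
    sb_sd: float = 5.0
    filter_fail_fraction: float = 0.02  # per criterion, per record (proband)
    site_fail_fraction: float = 0.03  # fraction of sites failing a PASS criterion


@dataclass
class CohortSpec:
    n_families: int = 2
    family_structures: list[FamilyStructure] = field(
        default_factory=lambda: [FamilyStructure(2, 4, 0), FamilyStructure(2, 2, 1)]
    )
    n_background_variants: int = 5000
    causal_chrom: str = "chr12"
    causal_pos: int = 22_063_090
    causal_ref: str = "C"
    causal_alt: str = "T"
    shared_block: tuple[int, int] = (18_326_590, 22_176_010)
    n_block_sites: int = 40
    background_af_beta: tuple[float, float] = (0.5, 3.0)  # Beta shape for AF/0.5
    quality_model: GenotypeQualityModel = field(default_factory=GenotypeQualityModel)
    n_de_novo: int = 0
    causal_gene: str = "GENE_CAUSAL"
    causal_population_af: float = 0.0007  # rare founder allele (one source)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.shared_block
        if not lo <= self.causal_pos <= hi:
            raise ValueError("shared block must contain the causal locus")
        if len(self.family_structures) != self.n_families:
            raise ValueError("one family structure per family required")


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

def _build_pedigree(spec: CohortSpec) -> Pedigree:
    inds: list[Individual] = []
    for fi, fs in enumerate(spec.family_structures, start=1):
        fid = f"FAM{fi}"
        father = Individual(fid, f"{fid}_F", sex=1)
        mother = Individual(fid, f"{fid}_M", sex=2)
        inds += [father, mother]
        for ci in range(fs.n_affected):
            inds.append(
                Individual(
                    fid, f"{fid}_A{ci + 1}", father.iid, mother.iid,
                    sex=1 + ci % 2, affected=True,
                )
            )
        for ci in range(fs.n_unaffected):
            inds.append(
                Individual(
                    fid, f"{fid}_U{ci + 1}", father.iid, mother.iid,
                    sex=1 + ci % 2, affected=False,
                )
            )
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# Genotype machinery
# ---------------------------------------------------------------------------

def _transmit(rng, father: tuple[int, int], mother: tuple[int, int]) -> tuple[int, int]:
    return (father[rng.integers(2)], mother[rng.integers(2)])


def _hwe_genotype(rng, af: float) -> tuple[int, int]:
    return (int(rng.random() < af), int(rng.random() < af))


def _call(
    rng,
    sample: str,
    alleles: tuple[int, int],
    qm: GenotypeQualityModel,
    is_indel: bool,
    clean: bool = False,
) -> GenotypeCall:
    dp = max(1, int(rng.gamma(qm.depth_shape, qm.depth_mean / qm.depth_shape)))
    if clean:
        dp = max(dp, 25)
        gq = qm.gq_high
    else:
        gq = (
            int(rng.integers(10, 99))
            if rng.random() < qm.gq_low_rate
            else qm.gq_high
        )
    n_alt = sum(alleles)
    c = qm.het_fraction_conc
    if n_alt == 1:
        vf = float(rng.beta(c / 2, c / 2))
    elif n_alt == 2:
        vf = float(rng.beta(c, 1.5))
    else:
        vf = float(rng.beta(1.5, c))
    sb = float(rng.normal(qm.sb_mean, qm.sb_sd))
    if clean:
        sb = min(sb, -15.0)
        vf = 0.5 if n_alt == 1 else (0.98 if n_alt == 2 else 0.01)
    r8 = float(rng.uniform(0, 5)) if is_indel else None
    return GenotypeCall(
        sample=sample, alleles=alleles, DP=dp, GQ=float(gq), GQX=float(gq),
        variant_read_fraction=round(vf, 3), SB=round(sb, 2), R8=r8,
    )


def _site_stats(rng, qm: GenotypeQualityModel, is_indel: bool, clean: bool) -> tuple[SiteStats, bool]:
    """Mostly-passing GATK site statistics; a ``site_fail_fraction`` of
    non-clean sites trips one randomly chosen criterion. Returns
    (stats, intended_pass)."""
    stats = SiteStats(
        QD=round(float(rng.uniform(5, 30)), 2),
        MQ=round(float(rng.uniform(50, 60)), 2),
        FS=round(float(rng.uniform(0, 20)), 2),
        HaplotypeScore=round(float(rng.uniform(0, 5)), 2),
        MQRankSum=round(float(rng.normal(0, 1.5)), 2),
        ReadPosRankSum=round(float(rng.normal(0, 1.5)), 2),
        snp_cluster_count=1,
        variant_class="indel" if is_indel else "snv",
    )
    if clean or rng.random() >= qm.site_fail_fraction:
        return stats, True
    which = rng.choice(["QD", "MQ", "FS", "ReadPosRankSum"])
    if which == "QD":
        stats.QD = round(float(rng.uniform(0.1, 1.9)), 2)
    elif which == "MQ":
        stats.MQ = round(float(rng.uniform(10, 39)), 2)
    elif which == "FS":
        stats.FS = round(float(rng.uniform(70, 250)), 2)
    else:
        stats.ReadPosRankSum = round(float(rng.uniform(-30, -21)), 2)
    return stats, stats.variant_class == "indel" and which in ("MQ",)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[VariantRecord], Pedigree, dict]:
    """Generate the cohort's variant records, pedigree and truth ledger.

    See the module docstring for the planted structure. The truth ledger
    records the causal variant key, the block bounds, planted de-novo keys,
    and per-stage expectations used by recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    qm = spec.quality_model
    ped = _build_pedigree(spec)
    samples = [i.iid for i in ped]
    parents = [i for i in ped if not i.has_parents]
    children = [i for i in ped if i.has_parents]

    records: list[VariantRecord] = []
    roi: list[tuple[str, int, int]] = []
    af_table: dict[tuple[str, int, str, str], dict[str, float]] = {}
    truth: dict = {
        "seed": spec.seed,
        "causal": list(
            (spec.causal_chrom, spec.causal_pos, spec.causal_ref, spec.causal_alt)
        ),
        "shared_block": [spec.causal_chrom, *spec.shared_block],
        "de_novo": [],
    }

    bases = np.array(list("ACGT"))

    def _snv_alleles(rng) -> tuple[str, str]:
        i, j = rng.choice(4, size=2, replace=False)
        return str(bases[i]), str(bases[j])

    # --- gene/exon scaffold: tile genes along two chromosomes -------------
    chroms = ["chr5", "chr12"]
    genes: list[dict] = []
    for chrom in chroms:
        for gi in range(60):
            start = 1_000_000 + gi * 500_000
            exon = (start + 10_000, start + 11_200)
            genes.append(
                {"chrom": chrom, "gene": f"GENE_{chrom[3:]}_{gi:03d}", "exon": exon}
            )
            roi.append((chrom, exon[0] - 1, exon[1]))  # BED half-open

    # --- causal variant: donor +1 of a dedicated exon ---------------------
    causal_exon = (spec.causal_pos - 1200, spec.causal_pos - 1)
    roi.append((spec.causal_chrom, causal_exon[0] - 1, causal_exon[1]))
    causal_calls = {}
    for ind in ped:
        alleles = (1, 1) if ind.affected else (0, 1)
        causal_calls[ind.iid] = _call(
            rng, ind.iid, alleles, qm, is_indel=False, clean=True
        )
    stats, _ = _site_stats(rng, qm, is_indel=False, clean=True)
    records.append(
        VariantRecord(
            chrom=spec.causal_chrom,
            pos=spec.causal_pos,
            ref=spec.causal_ref,
            alt=spec.causal_alt,
            calls=causal_calls,
            qual=3000.0,
            filter="PASS",
            stats=stats,
            gene=spec.causal_gene,
            effect="splice_region",
            boundary_offset=-1,  # first intronic base past the donor
        )
    )
    af_table[records[-1].key] = {"gnomAD": spec.causal_population_af}

    # --- shared-block sites: common SNPs, homozygous founder haplotype ----
    lo, hi = spec.shared_block
    interior = rng.choice(
        np.arange(lo + 1, hi), size=max(spec.n_block_sites - 2, 0), replace=False
    )
    # anchor sites at the exact block bounds so the planted extent is the
    # detectable extent
    block_positions = np.sort(np.concatenate([[lo, hi], interior]))
    block_positions = block_positions[block_positions != spec.causal_pos]
    for pos in block_positions:
        ref, alt = _snv_alleles(rng)
        founder_allele = int(rng.random() < 0.5)  # shared haplotype allele
        # every parent carries one copy of the founder haplotype plus an
        # independent random allele; children inherit by transmission, with
        # affected children receiving the founder haplotype from both sides
        parent_gt = {
            p.iid: tuple(sorted((founder_allele, int(rng.random() < 0.5))))
            for p in parents
        }
        calls = {}
        for ind in ped:
            if ind.affected:
                alleles = (founder_allele, founder_allele)
            elif not ind.has_parents:
                alleles = parent_gt[ind.iid]
            else:  # unaffected sibling: Mendelian transmission
                alleles = tuple(
                    sorted(
                        _transmit(
                            rng, parent_gt[ind.father_id], parent_gt[ind.mother_id]
                        )
                    )
                )
            calls[ind.iid] = _call(rng, ind.iid, alleles, qm, False, clean=True)
        stats, _ = _site_stats(rng, qm, False, clean=True)
        af = round(float(rng.uniform(0.05, 0.45)), 4)
        rec = VariantRecord(
            chrom=spec.causal_chrom, pos=int(pos), ref=ref, alt=alt,
            calls=calls, qual=2000.0, filter="PASS", stats=stats,
            gene=None, effect="noncoding", boundary_offset=None,
        )
        records.append(rec)
        af_table[rec.key] = {s: af for s in AF_SOURCES[:2]}

    # --- background variants ----------------------------------------------
    eff_names = list(EFFECT_WEIGHTS)
    eff_p = np.array(list(EFFECT_WEIGHTS.values()))
    eff_p = eff_p / eff_p.sum()
    a_beta, b_beta = spec.background_af_beta
    n_bg = spec.n_background_variants
    gene_idx = rng.integers(0, len(genes), size=n_bg)
    for i in range(n_bg):
        g = genes[int(gene_idx[i])]
        exon_start, exon_end = g["exon"]
        effect = str(rng.choice(eff_names, p=eff_p))
        in_roi = rng.random() < 0.9
        if effect == "splice_region":
            off = -int(rng.integers(1, 9))
            pos = exon_end - off  # intronic, downstream of the exon
            boundary_offset = off
        elif effect == "noncoding" or not in_roi:
            pos = exon_end + int(rng.integers(200, 5000))
            boundary_offset = -int(pos - exon_end)
            effect = "noncoding"
        else:
            pos = int(rng.integers(exon_start, exon_end + 1))
            boundary_offset = int(min(pos - exon_start, exon_end - pos) + 1)
        if g["chrom"] == spec.causal_chrom and lo <= pos <= hi:
            continue  # keep the block's rare-variant content controlled
        is_indel = rng.random() < 0.05
        ref, alt = _snv_alleles(rng)
        if is_indel:
            ref, alt = ref, ref + alt  # simple 1-bp insertion
        af = float(0.5 * rng.beta(a_beta, b_beta))
        # founder genotypes under HWE, children by transmission
        founder_gt = {p.iid: _hwe_genotype(rng, af) for p in parents}
        child_gt = {}
        for ch in children:
            child_gt[ch.iid] = _transmit(
                rng, founder_gt[ch.father_id], founder_gt[ch.mother_id]
            )
        calls = {}
        fail_criteria = [
            name
            for name in ("LowGQX", "LowVariantFreq", "LowGQ", "R8", "SB", "LowDP")
            if rng.random() < qm.filter_fail_fraction
        ]
        for ind in ped:
            alleles = founder_gt.get(ind.iid) or child_gt[ind.iid]
            alleles = tuple(sorted(alleles))
            c = _call(rng, ind.iid, alleles, qm, is_indel)
            if ind.affected and fail_criteria:
                for name in fail_criteria:
                    if name == "LowGQX":
                        c.GQX = float(rng.integers(1, 10))
                    elif name == "LowGQ":
                        c.GQ = float(rng.integers(10, 30))
                    elif name == "LowVariantFreq":
                        c.variant_read_fraction = round(float(rng.uniform(0.01, 0.19)), 3)
                    elif name == "R8" and is_indel:
                        c.R8 = round(float(rng.uniform(9, 20)), 2)
                    elif name == "SB":
                        c.SB = round(float(rng.uniform(-9, 5)), 2)
                    elif name == "LowDP":
                        c.DP = int(rng.integers(1, 20))
            calls[ind.iid] = c
        stats, _ = _site_stats(rng, qm, is_indel, clean=False)
        rec = VariantRecord(
            chrom=g["chrom"], pos=pos, ref=ref, alt=alt, calls=calls,
            qual=round(float(rng.uniform(500, 3000)), 1),
            stats=stats, gene=g["gene"], effect=effect,
            boundary_offset=boundary_offset,
        )
        from ..crossfam import flag_pass

        rec.filter = "PASS" if flag_pass(stats) else "FAIL"
        records.append(rec)
        if rng.random() < 0.9:  # most variants are known to AF databases
            n_src = int(rng.integers(1, len(AF_SOURCES) + 1))
            srcs = rng.choice(AF_SOURCES, size=n_src, replace=False)
            reported = max(af * float(rng.uniform(0.8, 1.2)), 1e-5)
            af_table[rec.key] = {str(s): round(reported, 6) for s in srcs}

    # --- optional de novo events ------------------------------------------
    affected_children = [c for c in children if c.affected]
    for _ in range(spec.n_de_novo):
        g = genes[int(rng.integers(0, len(genes)))]
        pos = int(rng.integers(g["exon"][0], g["exon"][1] + 1))
        ref, alt = _snv_alleles(rng)
        child = affected_children[int(rng.integers(0, len(affected_children)))]
        calls = {}
        for ind in ped:
            alleles = (0, 1) if ind.iid == child.iid else (0, 0)
            calls[ind.iid] = _call(rng, ind.iid, alleles, qm, False, clean=True)
        stats, _ = _site_stats(rng, qm, False, clean=True)
        rec = VariantRecord(
            chrom=g["chrom"], pos=pos, ref=ref, alt=alt, calls=calls,
            qual=1500.0, filter="PASS", stats=stats, gene=g["gene"],
            effect="nonsynonymous",
            boundary_offset=int(min(pos - g["exon"][0], g["exon"][1] - pos) + 1),
        )
        records.append(rec)
        truth["de_novo"].append([rec.chrom, rec.pos, rec.ref, rec.alt, child.iid])

    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    # drop duplicate (chrom,pos,ref,alt) collisions from random placement
    seen: set = set()
    unique_records = []
    for r in records:
        if r.key in seen:
            continue
        seen.add(r.key)
        unique_records.append(r)
    records = unique_records

    roi.sort()
    truth["roi_intervals"] = len(roi)
    truth["n_records"] = len(records)
    truth["samples"] = samples
    return records, ped, {"truth": truth, "roi": roi, "af_table": af_table}


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Simulate and serialize a cohort: VCF + PED + ROI BED + AF TSV +
    truth-ledger JSON. Returns the truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, ped, extra = simulate_cohort(spec)
    samples = [i.iid for i in ped]
    write_vcf(records, samples, out / "cohort.vcf")
    write_ped(ped, out / "cohort.ped")
    write_bed(extra["roi"], out / "roi.bed")
    write_af_table(extra["af_table"], out / "population_af.tsv")
    (out / "truth.json").write_text(json.dumps(extra["truth"], indent=1))
    return extra["truth"]


# ---------------------------------------------------------------------------
# Paired genotype panels for kinship testing
# ---------------------------------------------------------------------------

RELATIONSHIPS = ("monozygotic", "parent_offspring", "full_sibs", "unrelated")


def simulate_genotype_panel(
    n_snps: int,
    relationship: str,
    af_beta: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired 0/1/2 genotype vectors at independent SNPs under
    Hardy-Weinberg equilibrium, with the second sample derived from the
    first by the relationship's transmission rules.

    For ``full_sibs`` both samples descend from the same simulated parent
    pair (the first sample is still marginally Hardy-Weinberg).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if relationship not in RELATIONSHIPS:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}"
        )
    rng = np.random.default_rng(seed)
    a, b = af_beta
    p = 0.5 * rng.beta(a, b, size=n_snps)  # MAF spectrum in (0, 0.5)

    def hwe(size):
        return (rng.random((2, size)) < p).astype(int)

    if relationship == "monozygotic":
        h = hwe(n_snps)
        g1 = h.sum(axis=0)
        return g1, g1.copy()
    if relationship == "parent_offspring":
        parent = hwe(n_snps)
        g1 = parent.sum(axis=0)
        transmitted = parent[rng.integers(0, 2, size=n_snps), np.arange(n_snps)]
        other = (rng.random(n_snps) < p).astype(int)
        return g1, transmitted + other
    if relationship == "full_sibs":
        father = hwe(n_snps)
        mother = hwe(n_snps)
        idx = np.arange(n_snps)

        def child():
            fi = rng.integers(0, 2, size=n_snps)
            mi = rng.integers(0, 2, size=n_snps)
            return father[fi, idx] + mother[mi, idx]

        return child(), child()
    # unrelated
    return hwe(n_snps).sum(axis=0), hwe(n_snps).sum(axis=0)
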