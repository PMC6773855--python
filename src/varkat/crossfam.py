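"""Cross-family whole-genome analysis.

Given one sequenced case per family, these operations identify candidates
without parental data: variants shared by both cases, genes hit in both
cases (dominant model), genes with two or more heterozygous variants in each
case (compound-het candidates without phase), pairwise kinship to rule out
cryptic relatedness, and shared homozygous blocks that localize a recessive
founder haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .variants import GenotypeCall, SiteStats, VariantRecord

# GATK-style hard-filter criteria; a site is PASS iff no class-appropriate
# criterion trips. (name, attribute, threshold, direction)
SNV_PASS_CRITERIA = [
    ("QD", "QD", 2.0, "lt"),
    ("MQ", "MQ", 40.0, "lt"),
    ("FS", "FS", 60.0, "gt"),
    ("HaplotypeScore", "HaplotypeScore", 13.0, "gt"),
    ("MQRankSum", "MQRankSum", -12.5, "lt"),
    ("ReadPosRankSum", "ReadPosRankSum", -8.0, "lt"),
    ("SnpCluster", "snp_cluster_count", 3, "ge"),  # >= 3 SNVs in 35 bp
]
INDEL_PASS_CRITERIA = [
    ("QD", "QD", 2.0, "lt"),
    ("FS", "FS", 200.0, "gt"),
    ("ReadPosRankSum", "ReadPosRankSum", -20.0, "lt"),
]

SNP_CLUSTER_WINDOW_BP = 35
SNP_CLUSTER_MIN = 3


def flag_pass(stats: SiteStats) -> bool:
    """Site-level PASS flag: true iff no class-appropriate hard-filter
    criterion trips. A missing statistic skips that criterion."""
    criteria = INDEL_PASS_CRITERIA if stats.variant_class == "indel" else SNV_PASS_CRITERIA
    for _name, attr, thr, direction in criteria:
        value = getattr(stats, attr)
        if value is None:
            continue
        if direction == "lt" and value < thr:
            return False
        if direction == "gt" and value > thr:
            return False
        if direction == "ge" and value >= thr:
            return False
    return True


def annotate_snp_clusters(records: Sequence[VariantRecord]) -> None:
    """Set ``snp_cluster_count`` on each SNV record: the number of SNVs
    (including itself) within a sliding 35-bp window centred so that the
    record trips the cluster criterion if >= 3 SNVs fall in any 35-bp span
    containing it."""
    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in records:
        if not r.is_indel:
            by_chrom.setdefault(r.chrom, []).append(r)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r.pos)
        pos = np.array([r.pos for r in recs])
        for i, r in enumerate(recs):
            lo = int(np.searchsorted(pos, r.pos - SNP_CLUSTER_WINDOW_BP + 1))
            best = 1
            # max SNV count over all 35-bp windows containing this site
            for j in range(lo, i + 1):
                if pos[j] + SNP_CLUSTER_WINDOW_BP - 1 < r.pos:
                    continue
                k = int(np.searchsorted(pos, pos[j] + SNP_CLUSTER_WINDOW_BP, side="left"))
                best = max(best, k - j)
            r.stats.snp_cluster_count = best


def high_quality_genotype(call: GenotypeCall, site_pass: bool) -> bool:
    """Lenient high-quality genotype criterion for WGS cohort analysis:
    depth > 4 reads, site PASS, genotype quality > 98 (strict as printed)."""
    if call.is_missing:
        return False
    return (
        call.DP is not None
        and call.DP > 4
        and site_pass
        and call.GQ is not None
        and call.GQ > 98
    )


# ---------------------------------------------------------------------------
# Shared analyses
# ---------------------------------------------------------------------------

@dataclass
class SharedAnalysisResult:
    shared_het: list[tuple[VariantRecord, VariantRecord]] = field(default_factory=list)
    shared_hom: list[tuple[VariantRecord, VariantRecord]] = field(default_factory=list)

    @property
    def n_het(self) -> int:
        return len(self.shared_het)

    @property
    def n_hom(self) -> int:
        return len(self.shared_hom)

    @property
    def n_total(self) -> int:
        return self.n_het + self.n_hom


def shared_variants(
    case_a: Iterable[VariantRecord],
    case_b: Iterable[VariantRecord],
    sample_a: str,
    sample_b: str,
) -> SharedAnalysisResult:
    """Variants identical by (chrom, pos, ref, alt) in both cases.

    Zygosity class of a shared variant: homozygous only when
    homozygous-alternate in BOTH cases, else heterozygous-shared.
    Both inputs are assumed already quality/effect/MAF filtered.
    """
    a_map = {r.key: r for r in case_a}
    result = SharedAnalysisResult()
    for rb in case_b:
        ra = a_map.get(rb.key)
        if ra is None:
            continue
        hom_both = ra.call(sample_a).is_hom_alt and rb.call(sample_b).is_hom_alt
        (result.shared_hom if hom_both else result.shared_het).append((ra, rb))
    return result


def shared_genes_dominant(
    case_a: Iterable[VariantRecord], case_b: Iterable[VariantRecord]
) -> dict[str, tuple[list[VariantRecord], list[VariantRecord]]]:
    """Genes with >= 1 qualifying variant in each case; the variants need
    not be identical (dominant 'same gene, different variant' model)."""
    genes_a: dict[str, list[VariantRecord]] = {}
    genes_b: dict[str, list[VariantRecord]] = {}
    for r in case_a:
        if r.gene is not None:
            genes_a.setdefault(r.gene, []).append(r)
    for r in case_b:
        if r.gene is not None:
            genes_b.setdefault(r.gene, []).append(r)
    return {g: (genes_a[g], genes_b[g]) for g in genes_a.keys() & genes_b.keys()}


def shared_compound_het_genes(
    case_a: Iterable[VariantRecord],
    case_b: Iterable[VariantRecord],
    sample_a: str,
    sample_b: str,
) -> list[str]:
    """Genes with >= 2 qualifying heterozygous variants in each case.

    Without parental genotypes the trans configuration cannot be
    established; this is a candidate screen, not a phased compound-het call.
    """

    def _het_gene_counts(records, sample):
        counts: dict[str, int] = {}
        for r in records:
            if r.gene is None:
                continue
            call = r.calls.get(sample)
            if call is not None and call.is_het:
                counts[r.gene] = counts.get(r.gene, 0) + 1
        return counts

    ca = _het_gene_counts(case_a, sample_a)
    cb = _het_gene_counts(case_b, sample_b)
    return sorted(g for g in ca.keys() & cb.keys() if ca[g] >= 2 and cb[g] >= 2)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship(
    genotypes_a: Sequence[int], genotypes_b: Sequence[int], min_sites: int = 100
) -> float:
    """Robust pairwise kinship coefficient from biallelic genotype vectors
    (0/1/2 alternate-allele counts; negative values = missing).

    Uses the within-pair heterozygote-sharing estimator
    ``phi = (N_het,het - 2 * N_opposite_hom) / (N_het(a) + N_het(b))``
    computed over sites called in both samples. It is allele-frequency-free
    and has expectation 0.5 for duplicates/MZ twins, 0.25 for
    parent-offspring and full sibs, and 0 for unrelated pairs.
    """
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size < min_sites:
        raise ValueError(
            f"only {a.size} overlapping called sites; need >= {min_sites}"
        )
    n_het_a = int(np.sum(a == 1))
    n_het_b = int(np.sum(b == 1))
    n_het_het = int(np.sum((a == 1) & (b == 1)))
    n_opp_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    denom = n_het_a + n_het_b
    if denom == 0:
        raise ValueError("no heterozygous sites in either sample")
    return (n_het_het - 2.0 * n_opp_hom) / denom


# ---------------------------------------------------------------------------
# Shared homozygous blocks
# ---------------------------------------------------------------------------

@dataclass
class HomozygosityBlock:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_sites: int

    @property
    def length_bp(self) -> int:
        """Reported as end - start, matching the usual coordinate-difference
        convention for block sizes."""
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return round(self.length_bp / 1e6, 1)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def shared_homozygous_blocks(
    sites: Sequence[tuple[int, int, int]],
    chrom: str = "chr12",
    min_length_bp: int = 1_000_000,
    het_tolerance: int = 0,
    min_sites: int = 3,
) -> list[HomozygosityBlock]:
    """Maximal runs where both samples are homozygous for identical alleles.

    ``sites`` is a position-sorted sequence of (pos, genotype_a, genotype_b)
    with genotypes as 0/1/2 alternate-allele counts. A site extends a run
    when both genotypes are homozygous (0 or 2) and equal; up to
    ``het_tolerance`` interrupting non-matching sites are absorbed inside a
    run. Blocks shorter than ``min_length_bp`` or with fewer than
    ``min_sites`` matching sites are dropped.
    """
    positions = [s[0] for s in sites]
    if any(positions[i] > positions[i + 1] for i in range(len(positions) - 1)):
        raise ValueError("sites must be position-sorted")

    def _match(ga: int, gb: int) -> bool:
        return ga == gb and ga in (0, 2)

    blocks: list[HomozygosityBlock] = []
    i = 0
    n = len(sites)
    while i < n:
        if not _match(sites[i][1], sites[i][2]):
            i += 1
            continue
        start_pos = sites[i][0]
        end_pos = start_pos
        n_match = 1
        hets_used = 0
        j = i + 1
        pending = 0  # consecutive non-matching sites awaiting absorption
        while j < n:
            if _match(sites[j][1], sites[j][2]):
                hets_used += pending
                pending = 0
                end_pos = sites[j][0]
                n_match += 1
                j += 1
            else:
                if hets_used + pending + 1 > het_tolerance:
                    break
                pending += 1
                j += 1
        if end_pos - start_pos >= min_length_bp and n_match >= min_sites:
            blocks.append(HomozygosityBlock(chrom, start_pos, end_pos, n_match))
        i = j if j > i else i + 1
    return blocks


def block_containing(
    blocks: Iterable[HomozygosityBlock], chrom: str, pos: int
) -> Optional[HomozygosityBlock]:
    """The block containing a query variant, or None."""
    for b in blocks:
        if b.chrom == chrom and b.contains(pos):
            return b
    return None
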