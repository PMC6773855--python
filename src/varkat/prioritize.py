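"""Per-family (trio) rare-variant prioritization.

Replicates a diagnostic gene-panel analysis pipeline: per-call quality
filtering, restriction to a flanked region of interest, effect/splice-window
classification, population-frequency filtering, and trio inheritance-model
calling (recessive homozygous, compound heterozygous, de novo). Stages are
applied in that order and per-stage removal counts are reported.

Every quality criterion is a pure predicate on the proband's genotype call,
applied strictly with the printed inequality: a record is *removed* when the
criterion trips (e.g. LowDP trips when DP < 20, so DP = 20 survives).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .pedigree import Pedigree, Trio
from .variants import GenotypeCall, VariantRecord

#: criterion name -> (required call field, trips(value) predicate, indel_only)
QUALITY_CRITERIA = {
    "LowGQX": ("GQX", 10.0, "lt"),
    "LowVariantFreq": ("variant_read_fraction", 0.20, "lt"),
    "LowGQ": ("GQ", 30.0, "lt"),
    "R8": ("R8", 8.0, "gt"),  # indel-context metric; skipped for SNVs
    "SB": ("SB", -10.0, "gt"),
    "LowDP": ("DP", 20.0, "lt"),
}

INDEL_ONLY_CRITERIA = {"R8"}

DEFAULT_RETAINED_EFFECTS = ("LoF", "nonsynonymous", "inframe", "splice_region")


@dataclass
class FilterConfig:
    """Thresholds for the prioritization pipeline.

    ``quality_thresholds`` maps criterion name to the tripping threshold;
    the direction of each inequality is fixed by the criterion definition.
    """

    quality_thresholds: dict[str, float] = dc_field(
        default_factory=lambda: {k: v[1] for k, v in QUALITY_CRITERIA.items()}
    )
    max_maf: float = 0.01
    roi_flank_bp: int = 10  # gene panel default; whole-genome mode uses 100
    intronic_splice_window: int = 8
    exonic_splice_window: int = 3
    retained_effects: tuple[str, ...] = DEFAULT_RETAINED_EFFECTS
    parental_dp_floor: int = 10
    require_all_affected: bool = True

    def __post_init__(self) -> None:
        if self.roi_flank_bp < 0:
            raise ValueError("ROI flank must be >= 0")
        if not 0.0 <= self.max_maf <= 1.0:
            raise ValueError("max MAF must be in [0, 1]")

    @classmethod
    def wgs(cls, **kw) -> "FilterConfig":
        kw.setdefault("roi_flank_bp", 100)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def _criterion_trips(
    name: str, call: GenotypeCall, record: VariantRecord, threshold: float
) -> Optional[bool]:
    """True if the criterion removes the record, False if it passes,
    None if the needed field is missing (unevaluable)."""
    fld, _, direction = QUALITY_CRITERIA[name]
    if name in INDEL_ONLY_CRITERIA and not record.is_indel:
        return False  # metric undefined for SNVs; criterion skipped
    if name == "LowVariantFreq" and call.n_alt == 0:
        return False  # read fraction measures support for a called variant
    value = getattr(call, fld)
    if value is None:
        return None
    return value < threshold if direction == "lt" else value > threshold


def apply_quality_filters(
    records: Iterable[VariantRecord],
    config: FilterConfig,
    proband: str,
) -> tuple[list[VariantRecord], dict[str, int], list[VariantRecord]]:
    """Remove records whose proband call trips any quality criterion.

    Returns (survivors, per-criterion removal counts, unevaluable records).
    A record is removed iff >= 1 criterion trips; every tripped criterion is
    counted. Records missing a field a criterion needs are removed and
    reported separately as unevaluable. Input order is preserved.
    """
    survivors: list[VariantRecord] = []
    removal_counts = {name: 0 for name in config.quality_thresholds}
    unevaluable: list[VariantRecord] = []
    for rec in records:
        call = rec.calls.get(proband)
        if call is None or call.is_missing:
            unevaluable.append(rec)
            continue
        tripped = False
        missing = False
        for name, thr in config.quality_thresholds.items():
            res = _criterion_trips(name, call, rec, thr)
            if res is None:
                missing = True
            elif res:
                removal_counts[name] += 1
                tripped = True
        if missing and not tripped:
            unevaluable.append(rec)
        elif not tripped:
            survivors.append(rec)
    return survivors, removal_counts, unevaluable


# ---------------------------------------------------------------------------
# Region of interest
# ---------------------------------------------------------------------------

def restrict_to_roi(
    records: Iterable[VariantRecord],
    intervals: Iterable[tuple[str, int, int]],
    flank_bp: int,
) -> list[VariantRecord]:
    """Keep records whose position lies inside any interval expanded by
    ``flank_bp`` on both sides.

    Intervals are BED-style 0-based half-open; record positions are 1-based.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end < start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        lo = start - flank_bp  # still half-open after expansion
        hi = end + flank_bp
        if hi <= lo:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi)
    for t in trees.values():
        t.merge_overlaps(strict=False)
    return [
        rec
        for rec in records
        if rec.chrom in trees and trees[rec.chrom].overlaps(rec.pos - 1)
    ]


# ---------------------------------------------------------------------------
# Population frequency
# ---------------------------------------------------------------------------

def filter_by_population_frequency(
    records: Iterable[VariantRecord], max_maf: float
) -> list[VariantRecord]:
    """Remove records reported above ``max_maf`` in any population source.

    A variant absent from every source is retained: in rare-disease
    discovery, absence of frequency evidence means the variant is rare.
    """
    out = []
    for rec in records:
        for af in rec.population_afs.values():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} outside [0, 1]")
        if all(af <= max_maf for af in rec.population_afs.values()):
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Effect / splice classification
# ---------------------------------------------------------------------------

def splice_window_hit(
    boundary_offset: Optional[int],
    intronic_window: int = 8,
    exonic_window: int = 3,
) -> bool:
    """True if the variant lies within the splice-site analysis window:
    up to ``intronic_window`` bp into the intron or ``exonic_window`` bp
    into the exon, measured from the nearest intron-exon boundary.

    Offsets are signed (negative = intronic, -1 is the first intronic base;
    positive = exonic, +1 the boundary-adjacent exonic base).
    """
    if boundary_offset is None or boundary_offset == 0:
        return False
    if boundary_offset < 0:
        return -boundary_offset <= intronic_window
    return boundary_offset <= exonic_window


def classify_effect(record: VariantRecord, transcript) -> str:
    """Classify a variant's coding effect against a transcript model.

    Categories: LoF (frameshift / stopgain / startloss / stoploss),
    nonsynonymous, synonymous, inframe, splice_region, noncoding.
    Splice-window membership takes precedence for intronic variants and for
    exonic variants with no protein-changing consequence.
    """
    from .splicing import TranscriptModel

    assert isinstance(transcript, TranscriptModel)
    if transcript.cds_sequence is None:
        raise ValueError("transcript without CDS sequence cannot classify effects")
    offset = record.boundary_offset
    if offset is None:
        offset = transcript.boundary_offset(record.pos)
    c_pos = transcript.genomic_to_cdna(record.pos)
    if c_pos is None:  # intronic
        if splice_window_hit(offset):
            return "splice_region"
        return "noncoding"
    if record.is_indel:
        if abs(len(record.alt) - len(record.ref)) % 3 == 0:
            return "inframe"
        return "LoF"
    # exonic SNV: mutate the codon and compare residues
    cds = transcript.cds_sequence
    codon_idx = (c_pos - 1) // 3
    within = (c_pos - 1) % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    from Bio.Seq import Seq

    base = record.alt if transcript.strand == "+" else str(Seq(record.alt).complement())
    new_codon = codon[:within] + base + codon[within + 1 :]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if codon_idx == 0 and new_aa != "M":
        return "LoF"  # startloss
    if new_aa == "*" and old_aa != "*":
        return "LoF"  # stopgain
    if old_aa == "*" and new_aa != "*":
        return "LoF"  # stoploss
    if new_aa != old_aa:
        return "nonsynonymous"
    if splice_window_hit(offset):
        return "splice_region"
    return "synonymous"


def effect_qualifies(record: VariantRecord, config: FilterConfig) -> bool:
    """Stage predicate: retained effect category, or any variant inside the
    splice window (the splice-site analysis overrides the category list)."""
    if splice_window_hit(
        record.boundary_offset,
        config.intronic_splice_window,
        config.exonic_splice_window,
    ):
        return True
    return record.effect in config.retained_effects


# ---------------------------------------------------------------------------
# Inheritance models
# ---------------------------------------------------------------------------

def call_recessive_homozygous(record: VariantRecord, trio: Trio) -> Optional[bool]:
    """Candidate iff the proband is homozygous-alternate and both parents
    are heterozygous carriers. None when a member is missing (unevaluable)."""
    try:
        p = record.call(trio.proband.iid)
        f = record.call(trio.father.iid)
        m = record.call(trio.mother.iid)
    except KeyError:
        return None
    if p.is_missing or f.is_missing or m.is_missing:
        return None
    return p.is_hom_alt and f.is_het and m.is_het


def call_de_novo(
    record: VariantRecord, trio: Trio, parental_dp_floor: int = 10
) -> Optional[bool]:
    """Candidate iff the proband carries an alternate allele absent from
    both parents. Parents below the depth floor make the call unevaluable
    (a missed parental allele cannot be excluded)."""
    try:
        p = record.call(trio.proband.iid)
        f = record.call(trio.father.iid)
        m = record.call(trio.mother.iid)
    except KeyError:
        return None
    if p.is_missing or f.is_missing or m.is_missing:
        return None
    if (f.DP is None or f.DP < parental_dp_floor) or (
        m.DP is None or m.DP < parental_dp_floor
    ):
        return None
    return p.n_alt >= 1 and f.n_alt == 0 and m.n_alt == 0


def _parental_origin(record: VariantRecord, trio: Trio) -> Optional[str]:
    """Phase a proband-het variant by transmission.

    Returns "paternal"/"maternal" when exactly one parent carries the
    alternate allele, None when the origin is ambiguous (both or neither
    parent carries it, or calls are missing)."""
    try:
        p = record.call(trio.proband.iid)
        f = record.call(trio.father.iid)
        m = record.call(trio.mother.iid)
    except KeyError:
        return None
    if not p.is_het or p.is_missing or f.is_missing or m.is_missing:
        return None
    f_has, m_has = f.n_alt > 0, m.n_alt > 0
    if f_has and not m_has:
        return "paternal"
    if m_has and not f_has:
        return "maternal"
    return None


def call_compound_het(
    records: Iterable[VariantRecord], trio: Trio
) -> tuple[dict[str, list[VariantRecord]], list[VariantRecord]]:
    """Find genes carrying >= 2 proband-het variants in trans configuration
    (at least one inherited from each parent), phased by transmission.

    Variants whose parental origin is ambiguous (e.g. both parents
    heterozygous at the site) are excluded from pairing and returned
    separately.

    Returns (gene -> contributing variants, excluded-ambiguous variants).
    """
    by_gene: dict[str, dict[str, list[VariantRecord]]] = {}
    ambiguous: list[VariantRecord] = []
    for rec in records:
        if rec.gene is None:
            continue
        call = rec.calls.get(trio.proband.iid)
        if call is None or not call.is_het:
            continue
        origin = _parental_origin(rec, trio)
        if origin is None:
            ambiguous.append(rec)
            continue
        by_gene.setdefault(rec.gene, {"paternal": [], "maternal": []})[origin].append(rec)
    candidates = {
        gene: sides["paternal"] + sides["maternal"]
        for gene, sides in by_gene.items()
        if sides["paternal"] and sides["maternal"]
    }
    return candidates, ambiguous


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class FamilyReport:
    """Per-family prioritization result with per-stage survivor counts."""

    family_id: str
    stage_counts: dict[str, int]
    removal_counts: dict[str, int]
    recessive: list[VariantRecord]
    compound_het_genes: dict[str, list[VariantRecord]]
    de_novo: list[VariantRecord]

    @property
    def candidate_keys(self) -> set[tuple[str, int, str, str]]:
        keys = {r.key for r in self.recessive} | {r.key for r in self.de_novo}
        for recs in self.compound_het_genes.values():
            keys |= {r.key for r in recs}
        return keys


def run_family_analysis(
    records: list[VariantRecord],
    pedigree: Pedigree,
    config: FilterConfig,
    roi: Optional[list[tuple[str, int, int]]] = None,
    family_id: Optional[str] = None,
) -> FamilyReport:
    """Run the staged prioritization for one family.

    Stage order: quality -> ROI -> effect/splice -> MAF -> inheritance
    models. With several affected siblings, candidates are intersected
    across their trios when ``config.require_all_affected`` is set
    (a causal recessive variant must be present in every affected child).
    """
    fams = pedigree.families
    if family_id is None:
        if len(fams) != 1:
            raise ValueError("family_id required for multi-family pedigrees")
        family_id = next(iter(fams))
    members = {i.iid for i in fams[family_id]}
    trios = [t for t in pedigree.trios(affected_only=True) if t.proband.iid in members]
    if not trios:
        raise ValueError(f"no affected child with two genotyped parents in {family_id}")
    sample_ids = {s for t in trios for s in t.sample_ids}
    vcf_samples = set(records[0].calls) if records else set()
    if records and not sample_ids <= vcf_samples:
        raise ValueError(
            f"pedigree samples {sorted(sample_ids - vcf_samples)} absent from VCF"
        )

    stage_counts = {"input": len(records)}
    current = records
    removal_counts: dict[str, int] = {}

    # quality (per proband; with several probands a record must pass for all)
    for trio in trios:
        current, rc, _ = apply_quality_filters(current, config, trio.proband.iid)
        for k, v in rc.items():
            removal_counts[k] = removal_counts.get(k, 0) + v
    stage_counts["quality"] = len(current)

    if roi is not None:
        current = restrict_to_roi(current, roi, config.roi_flank_bp)
    stage_counts["roi"] = len(current)

    current = [r for r in current if effect_qualifies(r, config)]
    stage_counts["effect"] = len(current)

    current = filter_by_population_frequency(current, config.max_maf)
    stage_counts["maf"] = len(current)

    def _per_trio(caller):
        per = []
        for trio in trios:
            per.append({r.key for r in current if caller(r, trio)})
        if config.require_all_affected:
            keys = set.intersection(*per) if per else set()
        else:
            keys = per[0] if per else set()
        return [r for r in current if r.key in keys]

    recessive = _per_trio(lambda r, t: call_recessive_homozygous(r, t) is True)
    de_novo = _per_trio(
        lambda r, t: call_de_novo(r, t, config.parental_dp_floor) is True
    )

    ch_per_trio = [call_compound_het(current, t)[0] for t in trios]
    if config.require_all_affected:
        genes = set.intersection(*(set(d) for d in ch_per_trio)) if ch_per_trio else set()
    else:
        genes = set(ch_per_trio[0]) if ch_per_trio else set()
    compound_het = {g: ch_per_trio[0][g] for g in genes}

    stage_counts["recessive"] = len(recessive)
    stage_counts["compound_het_genes"] = len(compound_het)
    stage_counts["de_novo"] = len(de_novo)
    return FamilyReport(
        family_id=family_id,
        stage_counts=stage_counts,
        removal_counts=removal_counts,
        recessive=recessive,
        compound_het_genes=compound_het,
        de_novo=de_novo,
    )
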