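"""Trio prioritization: quality predicates, ROI, MAF, effects, inheritance."""

from __future__ import annotations

import numpy as np
import pytest

from varkat import prioritize
from varkat.pedigree import Individual, Pedigree
from varkat.prioritize import (
    FilterConfig,
    apply_quality_filters,
    call_compound_het,
    call_de_novo,
    call_recessive_homozygous,
    filter_by_population_frequency,
    restrict_to_roi,
    run_family_analysis,
    splice_window_hit,
)
from varkat.variants import GenotypeCall, VariantRecord


def _call(sample="P", alleles=(0, 1), DP=40, GQ=60.0, GQX=50.0, vf=0.5, SB=-30.0, R8=None):
    return GenotypeCall(
        sample=sample, alleles=alleles, DP=DP, GQ=GQ, GQX=GQX,
        variant_read_fraction=vf, SB=SB, R8=R8,
    )


def _record(pos=100, chrom="chr1", ref="A", alt="G", calls=None, **kw):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        calls=calls or {"P": _call()}, **kw,
    )


def _trio_pedigree():
    return Pedigree(
        [
            Individual("F1", "DAD", sex=1),
            Individual("F1", "MOM", sex=2),
            Individual("F1", "KID", "DAD", "MOM", sex=1, affected=True),
        ]
    )


class TestQualityFilters:
    @pytest.mark.parametrize(
        "field,value,reason",
        [
            ("GQX", 5.0, "LowGQX"),
            ("GQ", 29.9, "LowGQ"),
            ("variant_read_fraction", 0.19, "LowVariantFreq"),
            ("SB", -9.0, "SB"),
            ("DP", 19, "LowDP"),
        ],
    )
    def test_single_criterion_removes(self, field, value, reason):
        call = _call()
        setattr(call, field, value)
        rec = _record(calls={"P": call})
        surv, counts, _ = apply_quality_filters([rec], FilterConfig(), "P")
        assert surv == []
        assert counts[reason] == 1

    def test_all_passing_retained(self):
        rec = _record(calls={"P": _call(GQX=50, DP=40, vf=0.5, GQ=60)})
        surv, counts, unev = apply_quality_filters([rec], FilterConfig(), "P")
        assert surv == [rec]
        assert sum(counts.values()) == 0 and unev == []

    def test_strict_inequality_boundaries(self):
        """Inequalities apply exactly as printed: DP=19 removed, DP=20 kept;
        GQX=10 kept; cross-checked against a direct re-statement of each
        predicate."""
        kept = _record(pos=1, calls={"P": _call(DP=20, GQX=10.0, GQ=30.0, vf=0.20)})
        removed = _record(pos=2, calls={"P": _call(DP=19)})
        surv, _, _ = apply_quality_filters([kept, removed], FilterConfig(), "P")
        assert surv == [kept]
        # independent predicate oracle
        c = kept.calls["P"]
        assert not (c.GQX < 10 or c.variant_read_fraction < 0.2 or c.GQ < 30
                    or c.SB > -10 or c.DP < 20)

    def test_r8_applies_to_indels_only(self):
        snv = _record(pos=1, calls={"P": _call(R8=50.0)})
        indel = _record(pos=2, ref="A", alt="AT", calls={"P": _call(R8=50.0, vf=0.5)})
        surv, counts, _ = apply_quality_filters([snv, indel], FilterConfig(), "P")
        assert surv == [snv]
        assert counts["R8"] == 1

    def test_missing_field_unevaluable(self):
        rec = _record(calls={"P": _call(GQX=None)})
        surv, _, unev = apply_quality_filters([rec], FilterConfig(), "P")
        assert surv == [] and unev == [rec]

    def test_variant_fraction_skipped_for_hom_ref(self):
        rec = _record(calls={"P": _call(alleles=(0, 0), vf=0.01)})
        surv, _, _ = apply_quality_filters([rec], FilterConfig(), "P")
        assert surv == [rec]


class TestROI:
    def test_flank_boundary(self):
        # BED interval (10, 20] in 1-based terms covers 11..20
        iv = [("chr1", 10, 20)]
        inside = _record(pos=30)  # 20 + 10
        outside = _record(pos=31)
        assert restrict_to_roi([inside], iv, 10) == [inside]
        assert restrict_to_roi([outside], iv, 10) == []

    def test_empty_interval_set(self):
        assert restrict_to_roi([_record()], [], 10) == []

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            restrict_to_roi([_record()], [("chr1", 20, 10)], 0)

    def test_against_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        intervals = []
        for _ in range(20):
            s = int(rng.integers(0, 5000))
            intervals.append(("chr1", s, s + int(rng.integers(1, 300))))
        flank = 25
        records = [_record(pos=int(p)) for p in rng.integers(1, 6000, size=400)]
        got = {id(r) for r in restrict_to_roi(records, intervals, flank)}
        expected = set()
        for r in records:
            for c, s, e in intervals:
                if s + 1 - flank <= r.pos <= e + flank:
                    expected.add(id(r))
                    break
        assert got == expected


class TestPopulationFrequency:
    def test_rare_variant_retained(self):
        rec = _record(population_afs={"gnomAD": 0.0007})
        assert filter_by_population_frequency([rec], 0.01) == [rec]

    def test_common_in_one_source_removed(self):
        rec = _record(population_afs={"gnomAD": 0.0001, "ExAC": 0.05})
        assert filter_by_population_frequency([rec], 0.01) == []

    def test_absent_annotation_retained(self):
        rec = _record()
        assert filter_by_population_frequency([rec], 0.01) == [rec]

    def test_invalid_af_rejected(self):
        with pytest.raises(ValueError):
            filter_by_population_frequency([_record(population_afs={"x": 1.5})], 0.01)


class TestSpliceWindow:
    @pytest.mark.parametrize(
        "offset,expected",
        [(-1, True), (-8, True), (-9, False), (3, True), (4, False), (None, False)],
    )
    def test_window_membership(self, offset, expected):
        assert splice_window_hit(offset) is expected


class TestEffectClassification:
    def test_stopgain_is_lof(self, abcc9_like_transcript):
        tm = abcc9_like_transcript
        # find a codon whose single-base change creates a stop
        cds = tm.cds_sequence
        for c_pos in range(4, tm.cds_length - 3):
            idx = (c_pos - 1) // 3
            within = (c_pos - 1) % 3
            codon = cds[idx * 3 : idx * 3 + 3]
            for base in "ACGT":
                new = codon[:within] + base + codon[within + 1 :]
                if new in ("TAA", "TAG", "TGA") and codon not in ("TAA", "TAG", "TGA"):
                    g = tm.cdna_to_genomic(c_pos)
                    rec = _record(pos=g, ref=codon[within], alt=base)
                    assert prioritize.classify_effect(rec, tm) == "LoF"
                    return
        pytest.fail("no stopgain-creating substitution found")

    def test_inframe_deletion(self, abcc9_like_transcript):
        tm = abcc9_like_transcript
        g = tm.cdna_to_genomic(30)
        rec = _record(pos=g, ref="AGGG", alt="A")
        assert prioritize.classify_effect(rec, tm) == "inframe"

    def test_donor_plus_one_is_splice_region(self, abcc9_like_transcript):
        tm = abcc9_like_transcript
        pos = tm.exon(8).genomic_end + 1
        rec = _record(pos=pos, ref="G", alt="A")
        assert prioritize.classify_effect(rec, tm) == "splice_region"


class TestInheritanceModels:
    def _trio_record(self, kid, dad, mom, pos=100, gene="G1", dp=40):
        calls = {
            "KID": _call("KID", kid, DP=dp),
            "DAD": _call("DAD", dad, DP=dp),
            "MOM": _call("MOM", mom, DP=dp),
        }
        return _record(pos=pos, calls=calls, gene=gene)

    @pytest.fixture
    def trio(self):
        return _trio_pedigree().trios()[0]

    def test_recessive_homozygous(self, trio):
        assert call_recessive_homozygous(
            self._trio_record((1, 1), (0, 1), (0, 1)), trio
        ) is True
        assert call_recessive_homozygous(
            self._trio_record((1, 1), (0, 0), (0, 1)), trio
        ) is False
        assert call_recessive_homozygous(
            self._trio_record((0, 1), (0, 1), (0, 1)), trio
        ) is False

    def test_de_novo(self, trio):
        assert call_de_novo(self._trio_record((0, 1), (0, 0), (0, 0)), trio) is True
        assert call_de_novo(self._trio_record((0, 1), (0, 1), (0, 0)), trio) is False
        # low parental depth -> unevaluable
        assert call_de_novo(
            self._trio_record((0, 1), (0, 0), (0, 0), dp=5), trio
        ) is None

    def test_compound_het_trans_vs_cis(self, trio):
        paternal = self._trio_record((0, 1), (0, 1), (0, 0), pos=10)
        maternal = self._trio_record((0, 1), (0, 0), (0, 1), pos=20)
        maternal2 = self._trio_record((0, 1), (0, 0), (0, 1), pos=30)
        genes, _ = call_compound_het([paternal, maternal], trio)
        assert set(genes) == {"G1"}
        genes, _ = call_compound_het([maternal, maternal2], trio)  # cis
        assert genes == {}

    def test_compound_het_ambiguous_excluded(self, trio):
        both_het = self._trio_record((0, 1), (0, 1), (0, 1), pos=10)
        maternal = self._trio_record((0, 1), (0, 0), (0, 1), pos=20)
        genes, ambiguous = call_compound_het([both_het, maternal], trio)
        assert genes == {} and ambiguous == [both_het]

    def test_compound_het_matches_pair_enumeration_oracle(self, trio):
        """Random small gene sets: candidate genes equal an exhaustive
        enumeration over all variant pairs with opposite parental origin."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            records = []
            for i in range(int(rng.integers(2, 15))):
                gene = f"G{rng.integers(1, 4)}"
                kid = tuple(sorted(rng.integers(0, 2, size=2)))
                dad = tuple(sorted(rng.integers(0, 2, size=2)))
                mom = tuple(sorted(rng.integers(0, 2, size=2)))
                records.append(
                    self._trio_record(kid, dad, mom, pos=10 * (i + 1), gene=gene)
                )
            got = set(call_compound_het(records, trio)[0])
            # oracle: all pairs in the same gene with unambiguous opposite origin
            def origin(r):
                k, d, m = (r.calls[s] for s in ("KID", "DAD", "MOM"))
                if not k.is_het:
                    return None
                if d.n_alt > 0 and m.n_alt == 0:
                    return "P"
                if m.n_alt > 0 and d.n_alt == 0:
                    return "M"
                return None
            expected = set()
            for a in records:
                for b in records:
                    if a is not b and a.gene == b.gene:
                        if {origin(a), origin(b)} == {"P", "M"}:
                            expected.add(a.gene)
            assert got == expected


class TestPipeline:
    def test_planted_recessive_recovered_exactly(self, small_cohort):
        spec, records, ped, extra = small_cohort
        cfg = FilterConfig()
        for fam in ("FAM1", "FAM2"):
            rep = run_family_analysis(records, ped, cfg, roi=extra["roi"], family_id=fam)
            assert [r.key for r in rep.recessive] == [tuple(extra["truth"]["causal"])]

    def test_zero_maf_keeps_only_unannotated(self, small_cohort):
        _, records, _, _ = small_cohort
        surv = filter_by_population_frequency(records, 0.0)
        assert all(not r.population_afs for r in surv)

    def test_multi_proband_intersection_is_subset(self, small_cohort):
        spec, records, ped, extra = small_cohort
        strict = run_family_analysis(
            records, ped, FilterConfig(require_all_affected=True),
            roi=extra["roi"], family_id="FAM1",
        )
        loose = run_family_analysis(
            records, ped, FilterConfig(require_all_affected=False),
            roi=extra["roi"], family_id="FAM1",
        )
        assert {r.key for r in strict.recessive} <= {r.key for r in loose.recessive}

    def test_survivors_match_predicate_conjunction_oracle(self, small_cohort):
        """The staged pipeline's post-MAF survivor set equals a one-pass
        brute-force conjunction of all predicates on every record."""
        spec, records, ped, extra = small_cohort
        cfg = FilterConfig()
        trio = [t for t in ped.trios() if t.proband.family_id == "FAM1"][0]
        q, _, _ = apply_quality_filters(records, cfg, trio.proband.iid)
        staged = filter_by_population_frequency(
            [r for r in restrict_to_roi(q, extra["roi"], cfg.roi_flank_bp)
             if prioritize.effect_qualifies(r, cfg)],
            cfg.max_maf,
        )
        oracle = []
        from intervaltree import IntervalTree
        for r in records:
            c = r.calls[trio.proband.iid]
            quality_ok = not (
                c.GQX < 10
                or (c.n_alt > 0 and c.variant_read_fraction < 0.2)
                or c.GQ < 30
                or (r.is_indel and c.R8 is not None and c.R8 > 8)
                or c.SB > -10
                or c.DP < 20
            ) and None not in (c.GQX, c.GQ, c.SB, c.DP) and not (
                r.is_indel and c.R8 is None
            )
            roi_ok = any(
                r.chrom == ch and s + 1 - cfg.roi_flank_bp <= r.pos <= e + cfg.roi_flank_bp
                for ch, s, e in extra["roi"]
            )
            eff_ok = prioritize.effect_qualifies(r, cfg)
            maf_ok = all(af <= cfg.max_maf for af in r.population_afs.values())
            if quality_ok and roi_ok and eff_ok and maf_ok:
                oracle.append(r.key)
        assert [r.key for r in staged] == oracle

    def test_relaxing_threshold_never_shrinks_survivors(self, small_cohort):
        spec, records, ped, extra = small_cohort
        base = FilterConfig()
        relaxed = FilterConfig(
            quality_thresholds={**base.quality_thresholds, "LowDP": 10.0},
            max_maf=0.05,
        )
        trio = ped.trios()[0]
        s_base, _, _ = apply_quality_filters(records, base, trio.proband.iid)
        s_rel, _, _ = apply_quality_filters(records, relaxed, trio.proband.iid)
        assert {r.key for r in s_base} <= {r.key for r in s_rel}

    def test_sample_mismatch_raises(self, small_cohort):
        _, records, _, extra = small_cohort
        bad_ped = _trio_pedigree()
        with pytest.raises(ValueError):
            run_family_analysis(records, bad_ped, FilterConfig(), family_id="F1")
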