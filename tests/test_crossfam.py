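"""Cross-family analysis: PASS flags, shared sets, kinship, ROH blocks."""

from __future__ import annotations

import numpy as np
import pytest

from varkat.crossfam import (
    HomozygosityBlock,
    block_containing,
    flag_pass,
    high_quality_genotype,
    kinship,
    shared_compound_het_genes,
    shared_genes_dominant,
    shared_homozygous_blocks,
    shared_variants,
)
from varkat.simulate import simulate_genotype_panel
from varkat.variants import GenotypeCall, SiteStats, VariantRecord


def _stats(**kw):
    base = dict(QD=20.0, MQ=60.0, FS=5.0, HaplotypeScore=1.0,
                MQRankSum=0.0, ReadPosRankSum=0.0, snp_cluster_count=1)
    base.update(kw)
    return SiteStats(**base)


def _case_record(sample, alleles, pos=100, gene="G1", chrom="chr1", ref="A", alt="G"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        calls={sample: GenotypeCall(sample=sample, alleles=alleles)},
    )


class TestPassFlag:
    def test_snv_low_qd_fails(self):
        assert flag_pass(_stats(QD=1.5)) is False

    def test_fs_threshold_depends_on_class(self):
        assert flag_pass(_stats(FS=150.0, variant_class="indel")) is True
        assert flag_pass(_stats(FS=150.0)) is False

    def test_all_clear_passes(self):
        assert flag_pass(_stats()) is True

    def test_snp_cluster_trips(self):
        assert flag_pass(_stats(snp_cluster_count=3)) is False

    def test_missing_statistic_skipped(self):
        assert flag_pass(SiteStats(QD=None, MQ=None)) is True

    @pytest.mark.parametrize(
        "kw", [dict(MQ=39.0), dict(HaplotypeScore=14.0), dict(MQRankSum=-13.0),
               dict(ReadPosRankSum=-9.0)]
    )
    def test_each_snv_criterion(self, kw):
        assert flag_pass(_stats(**kw)) is False


class TestHighQualityGenotype:
    def _call(self, DP=5, GQ=99.0):
        return GenotypeCall(sample="s", alleles=(0, 1), DP=DP, GQ=GQ)

    def test_lenient_criteria_strict_inequalities(self):
        assert high_quality_genotype(self._call(DP=5, GQ=99), True) is True
        assert high_quality_genotype(self._call(DP=4), True) is False
        assert high_quality_genotype(self._call(GQ=98.0), True) is False
        assert high_quality_genotype(self._call(), False) is False


class TestSharedVariants:
    def test_zygosity_classes(self):
        a_het = _case_record("A", (0, 1), pos=1)
        b_het = _case_record("B", (0, 1), pos=1)
        a_hom = _case_record("A", (1, 1), pos=2)
        b_hom = _case_record("B", (1, 1), pos=2)
        only_a = _case_record("A", (0, 1), pos=3)
        res = shared_variants([a_het, a_hom, only_a], [b_het, b_hom], "A", "B")
        assert res.n_het == 1 and res.n_hom == 1 and res.n_total == 2

    def test_hom_in_one_case_only_is_het_shared(self):
        a = _case_record("A", (1, 1), pos=1)
        b = _case_record("B", (0, 1), pos=1)
        res = shared_variants([a], [b], "A", "B")
        assert res.n_het == 1 and res.n_hom == 0

    def test_planted_hom_among_decoys(self):
        """One planted shared-hom among 500 shared-het decoys counts (500, 1);
        cross-checked with a raw set intersection."""
        case_a, case_b = [], []
        for i in range(500):
            case_a.append(_case_record("A", (0, 1), pos=10 + i))
            case_b.append(_case_record("B", (0, 1), pos=10 + i))
        case_a.append(_case_record("A", (1, 1), pos=9000))
        case_b.append(_case_record("B", (1, 1), pos=9000))
        case_a.append(_case_record("A", (0, 1), pos=9999))  # private to A
        res = shared_variants(case_a, case_b, "A", "B")
        assert (res.n_het, res.n_hom) == (500, 1)
        assert len({r.key for r in case_a} & {r.key for r in case_b}) == 501

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        case_a = [_case_record("S", tuple(sorted(rng.integers(0, 2, 2))), pos=int(p))
                  for p in rng.choice(1000, 50, replace=False)]
        case_b = [_case_record("S", tuple(sorted(rng.integers(0, 2, 2))), pos=int(p))
                  for p in rng.choice(1000, 50, replace=False)]
        ab = shared_variants(case_a, case_b, "S", "S")
        ba = shared_variants(case_b, case_a, "S", "S")
        assert (ab.n_het, ab.n_hom) == (ba.n_het, ba.n_hom)


class TestSharedGenes:
    def test_distinct_variants_same_gene_included(self):
        a = [_case_record("A", (0, 1), pos=1, gene="G1")]
        b = [_case_record("B", (0, 1), pos=2, gene="G1")]
        assert set(shared_genes_dominant(a, b)) == {"G1"}

    def test_gene_in_one_case_excluded(self):
        a = [_case_record("A", (0, 1), pos=1, gene="G1")]
        assert shared_genes_dominant(a, []) == {}

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(2)
        def random_case(sample):
            return [
                _case_record(sample, (0, 1), pos=int(p), gene=f"G{rng.integers(1, 8)}")
                for p in rng.choice(10_000, 60, replace=False)
            ]
        a, b = random_case("A"), random_case("B")
        got = set(shared_genes_dominant(a, b))
        expected = {r.gene for r in a} & {r.gene for r in b}
        assert got == expected


class TestSharedCompoundHet:
    def test_two_hets_each_included(self):
        a = [_case_record("A", (0, 1), pos=p, gene="G1") for p in (1, 2)]
        b = [_case_record("B", (0, 1), pos=p, gene="G1") for p in (3, 4)]
        assert shared_compound_het_genes(a, b, "A", "B") == ["G1"]

    def test_one_het_in_b_excluded(self):
        a = [_case_record("A", (0, 1), pos=p, gene="G1") for p in (1, 2)]
        b = [_case_record("B", (0, 1), pos=3, gene="G1")]
        assert shared_compound_het_genes(a, b, "A", "B") == []

    def test_hom_calls_do_not_count(self):
        a = [_case_record("A", (1, 1), pos=1, gene="G1"),
             _case_record("A", (0, 1), pos=2, gene="G1")]
        b = [_case_record("B", (0, 1), pos=p, gene="G1") for p in (3, 4)]
        assert shared_compound_het_genes(a, b, "A", "B") == []

    def test_subset_of_dominant_shared_genes(self):
        rng = np.random.default_rng(3)
        def random_case(sample):
            return [
                _case_record(
                    sample, tuple(sorted(rng.integers(0, 2, 2))), pos=int(p),
                    gene=f"G{rng.integers(1, 6)}",
                )
                for p in rng.choice(10_000, 80, replace=False)
            ]
        a, b = random_case("A"), random_case("B")
        a = [r for r in a if r.calls["A"].n_alt > 0]
        b = [r for r in b if r.calls["B"].n_alt > 0]
        comphet = set(shared_compound_het_genes(a, b, "A", "B"))
        dominant = set(shared_genes_dominant(a, b))
        assert comphet <= dominant


class TestKinship:
    def test_duplicate_sample_limit(self):
        g = np.array([0, 1, 2, 1, 0, 1] * 40)
        assert kinship(g, g) == 0.5

    @pytest.mark.parametrize(
        "relationship,expected",
        [("monozygotic", 0.5), ("parent_offspring", 0.25),
         ("full_sibs", 0.25), ("unrelated", 0.0)],
    )
    def test_recovery_on_simulated_pairs(self, relationship, expected):
        g1, g2 = simulate_genotype_panel(10_000, relationship, seed=17)
        assert abs(kinship(g1, g2) - expected) <= 0.02

    def test_symmetry(self):
        g1, g2 = simulate_genotype_panel(2_000, "full_sibs", seed=8)
        assert kinship(g1, g2) == pytest.approx(kinship(g2, g1))

    def test_too_few_sites_raises(self):
        with pytest.raises(ValueError):
            kinship(np.array([0, 1]), np.array([1, 1]))


class TestHomozygosityBlocks:
    def test_het_terminates_block(self):
        sites = [(p, 2, 2) for p in range(100, 901, 100)] + [(950, 1, 2)]
        blocks = shared_homozygous_blocks(sites, min_length_bp=100, min_sites=3)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (100, 900)

    def test_printed_coordinates_round_to_3_8_mb(self):
        b = HomozygosityBlock("chr12", 18_326_590, 22_176_010, n_sites=100)
        assert b.length_bp == 3_849_420
        assert b.length_mb == 3.8

    def test_matches_bruteforce_scan(self):
        """Detection equals a brute-force enumeration of maximal matching
        runs on random dense chromosomes (het tolerance 0)."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            pos = np.sort(rng.choice(100_000, size=300, replace=False)) + 1
            ga = rng.choice([0, 1, 2], size=300, p=[0.4, 0.2, 0.4])
            gb = rng.choice([0, 1, 2], size=300, p=[0.4, 0.2, 0.4])
            sites = list(zip(pos.tolist(), ga.tolist(), gb.tolist()))
            got = shared_homozygous_blocks(sites, min_length_bp=500, min_sites=2)
            match = [a == b and a in (0, 2) for _, a, b in sites]
            expected = []
            i = 0
            while i < len(sites):
                if not match[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < len(sites) and match[j + 1]:
                    j += 1
                if pos[j] - pos[i] >= 500 and j - i + 1 >= 2:
                    expected.append((int(pos[i]), int(pos[j]), j - i + 1))
                i = j + 1
            assert [(b.start, b.end, b.n_sites) for b in got] == expected

    def test_het_tolerance_absorbs_single_interruption(self):
        sites = [(100, 2, 2), (200, 2, 2), (300, 1, 2), (400, 2, 2), (500, 2, 2)]
        strict = shared_homozygous_blocks(sites, min_length_bp=100, min_sites=2)
        tol = shared_homozygous_blocks(
            sites, min_length_bp=100, min_sites=2, het_tolerance=1
        )
        assert [(b.start, b.end) for b in strict] == [(100, 200), (400, 500)]
        assert [(b.start, b.end) for b in tol] == [(100, 500)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            shared_homozygous_blocks([(200, 2, 2), (100, 2, 2)])

    def test_planted_block_recovered_in_cohort(self, small_cohort):
        """The planted founder block is recovered with its exact anchored
        bounds from the cohort's informative (common) chr12 sites."""
        spec, records, _, extra = small_cohort
        sites = []
        for r in sorted((r for r in records if r.chrom == "chr12"), key=lambda r: r.pos):
            if not r.population_afs or max(r.population_afs.values()) < 0.05:
                continue
            sites.append((r.pos, r.calls["FAM1_A1"].n_alt, r.calls["FAM2_A1"].n_alt))
        blocks = shared_homozygous_blocks(sites, chrom="chr12")
        truth_lo, truth_hi = spec.shared_block
        hit = block_containing(blocks, "chr12", spec.causal_pos)
        assert hit is not None
        # bounds within one inter-variant gap of the planted extent
        gaps = np.diff([p for p, _, _ in sites])
        assert abs(hit.start - truth_lo) <= gaps.max()
        assert abs(hit.end - truth_hi) <= gaps.max()
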