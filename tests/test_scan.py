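"""Scan model: tables, strict-segregation classification, significance."""

from math import comb

import numpy as np
import pytest

from sexscan.scan import (
    ScanConfig,
    SegregationClass,
    SexGenotypeTable,
    SexLinkageModel,
    classify_segregation,
    genotype_table,
    rescan_region,
    scan_genome,
)
from sexscan.io import MISSING, filter_biallelic, VariantClass

from conftest import make_matrix, make_samples, strict_site_calls


def _table(f, m, nf=None, nm=None):
    return SexGenotypeTable(f, m, nf or sum(f), nm or sum(m))


class TestGenotypeTable:
    def test_strict_site_counts(self):
        samples = make_samples(16, 15)
        m = make_matrix(
            [("sc", 1, "A", ["T"], strict_site_calls(16, 15))], samples
        )
        t = genotype_table(0, m)
        assert t.female_counts == (16, 0, 0)
        assert t.male_counts == (0, 15, 0)

    def test_missing_and_unknown_excluded(self):
        samples = make_samples(2, 2, n_unknown=1)
        calls = [0, MISSING, 1, 1, 2]  # unknown sample has hom_alt, ignored
        m = make_matrix([("sc", 1, "A", ["T"], calls)], samples)
        t = genotype_table(0, m)
        assert t.female_counts == (1, 0, 0)
        assert t.male_counts == (0, 2, 0)

    def test_all_missing(self):
        samples = make_samples(2, 2)
        m = make_matrix([("sc", 1, "A", ["T"], [MISSING] * 4)], samples)
        t = genotype_table(0, m)
        assert t.female_counts == (0, 0, 0) and t.male_counts == (0, 0, 0)


class TestClassifySegregation:
    @pytest.mark.parametrize(
        "f,m,expected",
        [
            ((16, 0, 0), (0, 15, 0), SegregationClass.MALE_HET),
            ((0, 0, 16), (0, 15, 0), SegregationClass.MALE_HET),  # hom_alt females
            ((16, 0, 0), (15, 0, 0), SegregationClass.NONE),
            ((0, 16, 0), (15, 0, 0), SegregationClass.FEMALE_HET),
            ((8, 8, 0), (0, 15, 0), SegregationClass.NONE),
            ((16, 0, 0), (0, 14, 1), SegregationClass.NONE),
        ],
    )
    def test_classes(self, f, m, expected):
        assert classify_segregation(_table(f, m)) == expected

    def test_row_swap_mirror(self):
        """male_het on a table iff female_het on the row-swapped table."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            f = tuple(rng.integers(0, 6, 3))
            m = tuple(rng.integers(0, 6, 3))
            if sum(f) == 0 or sum(m) == 0:
                continue
            t = _table(f, m)
            sw = t.swapped()
            c1, c2 = classify_segregation(t), classify_segregation(sw)
            mirror = {
                SegregationClass.MALE_HET: SegregationClass.FEMALE_HET,
                SegregationClass.FEMALE_HET: SegregationClass.MALE_HET,
                SegregationClass.NONE: SegregationClass.NONE,
            }
            assert c2 == mirror[c1]

    def test_call_fraction_guard(self):
        cfg = ScanConfig(min_call_fraction_per_sex=0.8)
        t = SexGenotypeTable((16, 0, 0), (0, 11, 0), 16, 15)  # 11/15 < 0.8
        assert classify_segregation(t, cfg) == SegregationClass.NONE


class TestScanGenome:
    def _cohort_matrix(self, nf, nm, extra_sites=()):
        samples = make_samples(nf, nm)
        specs = [("sc", 100, "A", ["T"], strict_site_calls(nf, nm))]
        specs += list(extra_sites)
        return make_matrix(specs, samples)

    def test_planted_strict_site_significant(self):
        m = self._cohort_matrix(16, 15)
        assocs = scan_genome(m)
        a = assocs[0]
        assert a.fisher_p == pytest.approx(1 / comb(31, 16), rel=1e-9)
        assert a.significant and a.sex_specific
        assert a.segregation == SegregationClass.MALE_HET

    @pytest.mark.parametrize(
        "nf,nm,expect_significant",
        [(14, 14, True), (13, 13, False)],
    )
    def test_threshold_boundary(self, nf, nm, expect_significant):
        """1/C(28,14) < 5e-8 <= 1/C(26,13): the cohort-size boundary."""
        assocs = scan_genome(self._cohort_matrix(nf, nm))
        assert assocs[0].significant is expect_significant

    def test_monomorphic_sites_not_significant(self):
        samples = make_samples(4, 4)
        m = make_matrix(
            [("sc", i + 1, "A", ["T"], [0] * 8) for i in range(5)], samples
        )
        assocs = scan_genome(m)
        assert all(a.fisher_p == 1.0 and not a.significant for a in assocs)

    def test_hwe_filter_blocks_extreme_het_excess(self):
        """An all-het site fails the HWE filter in the all-samples scope
        (31 heterozygotes is a wild departure from HWE)."""
        samples = make_samples(16, 15)
        m = make_matrix([("sc", 1, "A", ["T"], [1] * 31)], samples)
        assocs = scan_genome(m, ScanConfig(hwe_scope="all_samples"))
        assert assocs[0].hwe_p < 1e-4
        assert not assocs[0].significant
        # in the female-only scope the 16-het stratum sits just above the
        # 1e-4 cut, so a true sex-linked site is not disqualified
        assocs_f = scan_genome(m, ScanConfig(hwe_scope="females_only"))
        assert assocs_f[0].hwe_p >= 1e-4

    def test_empty_stratum_propagates(self):
        samples = make_samples(2, 2)
        m = make_matrix([("sc", 1, "A", ["T"], [0, 0, MISSING, MISSING])], samples)
        with pytest.raises(ValueError, match="empty sex stratum"):
            scan_genome(m)


class TestModelResults:
    def test_results_surface(self, small_cohort):
        _, cohort = small_cohort
        matrix = filter_biallelic(cohort.matrix, {VariantClass.SNP})
        res = SexLinkageModel(matrix).fit()
        df = res.frame()
        assert len(df) == matrix.n_sites
        assert res.heterogametic_system() == "XY"
        assert "Heterogametic system:     XY" in res.summary()
        man = res.manhattan_frame()
        assert (man["neg_log10_p"] >= 0).all()
        assert man["cumulative_position"].is_monotonic_increasing

    def test_zw_cohort_classifies_female_het(self):
        from sexscan.simulate import CohortConfig, SDRegionConfig, simulate_cohort

        cfg = CohortConfig(
            n_background_sites=50,
            scaffolds=(("scaffold_003", 200_000),),
            sd_region=SDRegionConfig(scaffold="scaffold_003", start=100_000),
            system="ZW",
            missing_rate=0.0,
            core_indel_length=0,
            seed=5,
        )
        _, cohort = cfg, simulate_cohort(cfg)
        matrix = filter_biallelic(cohort.matrix, {VariantClass.SNP})
        res = SexLinkageModel(matrix).fit()
        core = [
            a
            for a in res.associations
            if cohort.truth.class_of(a.site.scaffold, a.site.position) == "core"
        ]
        assert core and all(
            a.segregation == SegregationClass.FEMALE_HET for a in core
        )
        assert res.heterogametic_system() == "ZW"


class TestRescanRegion:
    def test_indel_recovered_in_window(self):
        samples = make_samples(16, 15)
        calls = strict_site_calls(16, 15)
        m = make_matrix(
            [
                ("sc", 100, "A", ["T"], calls),
                ("sc", 200, "GTAATGTAG", ["G"], calls),
                ("sc", 90_000, "C", ["G"], [0] * 31),
            ],
            samples,
        )
        assocs = rescan_region(m, "sc", (50, 500))
        assert [a.site.position for a in assocs] == [100, 200]
        indel = assocs[1]
        assert indel.sex_specific
        assert indel.fisher_p == pytest.approx(1 / comb(31, 16), rel=1e-9)

    def test_empty_window_is_empty_list(self):
        samples = make_samples(2, 2)
        m = make_matrix([("sc", 100, "A", ["T"], [0, 0, 1, 1])], samples)
        assert rescan_region(m, "sc", (500, 900)) == []
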