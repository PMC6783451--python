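"""In-silico PCR binding model, sex calling, and assay accuracy."""

import numpy as np
import pytest

from sexscan.assay import (
    AssayKind,
    AssayProduct,
    AssayRule,
    CallValue,
    PrimerPair,
    assay_accuracy,
    call_sex,
    design_flanking_primers,
    haplotype_templates,
    insilico_pcr,
    reverse_complement,
)
from sexscan.io import Sex, VariantSite


def _pair(forward, reverse, name="p"):
    return PrimerPair(name, forward, (reverse,))


class TestInsilicoPCR:
    # 20 bp chosen so the 6-bp end primers have no off-target bindings
    # under the lenient mismatch allowance
    TEMPLATE = "CTGACTGATGTAATAGACCC"

    def test_full_span_amplicon(self):
        fwd = self.TEMPLATE[:6]
        rev = reverse_complement(self.TEMPLATE[-6:])
        products = insilico_pcr(_pair(fwd, rev), [self.TEMPLATE])
        assert [p.length_bp for p in products] == [20]

    def test_three_prime_anchor_mismatch_kills_binding(self):
        fwd = self.TEMPLATE[:5] + ("G" if self.TEMPLATE[5] != "G" else "C")
        rev = reverse_complement(self.TEMPLATE[-6:])
        assert insilico_pcr(_pair(fwd, rev), [self.TEMPLATE]) == []

    def test_internal_mismatches_tolerated_up_to_two(self):
        fwd = list(self.TEMPLATE[:8])
        fwd[1] = "T" if fwd[1] != "T" else "A"
        fwd[3] = "C" if fwd[3] != "C" else "G"
        rev = reverse_complement(self.TEMPLATE[-6:])
        products = insilico_pcr(_pair("".join(fwd), rev), [self.TEMPLATE])
        assert [p.length_bp for p in products] == [20]
        fwd[4] = "G" if fwd[4] != "G" else "T"  # third mismatch
        assert insilico_pcr(_pair("".join(fwd), rev), [self.TEMPLATE]) == []

    def test_het_deletion_two_products_differ_by_indel_length(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), 200))
        deletion = 8
        alt = ref[:96] + ref[96 + deletion :]  # drop 8 bp
        fwd = ref[10:30]
        rev = reverse_complement(ref[160:180])
        products = insilico_pcr(_pair(fwd, rev), [ref, alt])
        lengths = sorted(p.length_bp for p in products)
        assert len(lengths) == 2
        assert lengths[1] - lengths[0] == deletion

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        template = "".join(rng.choice(list("ACGT"), 120))
        fwd = template[5:25]
        rev = reverse_complement(template[90:110])
        direct = {p.length_bp for p in insilico_pcr(_pair(fwd, rev), [template])}
        flipped = {
            p.length_bp
            for p in insilico_pcr(
                _pair(rev, fwd), [reverse_complement(template)]
            )
        }
        assert direct == flipped != set()

    def test_template_shorter_than_primer(self):
        assert insilico_pcr(_pair("ACGTACGTACGT", "ACGTACGTACGT"), ["ACG"]) == []

    def test_max_product_cap(self):
        rng = np.random.default_rng(4)
        template = "".join(rng.choice(list("ACGT"), 3000))
        fwd = template[0:20]
        rev = reverse_complement(template[2500:2520])
        assert insilico_pcr(_pair(fwd, rev), [template]) == []


class TestTemplatesAndDesign:
    def test_haplotype_templates_het_snp(self):
        ref = "AAAACCCCGGGGTTTT"
        site = VariantSite("sc", 6, "C", ("T",))
        h0, h1 = haplotype_templates(ref, [site], [1], (1, 16))
        assert h0 == ref
        assert h1 == "AAAACTCCGGGGTTTT"

    def test_flanking_design_products(self):
        rng = np.random.default_rng(12)
        ref = "".join(rng.choice(list("ACGT"), 400))
        site = VariantSite("sc", 200, ref[199:208], (ref[199],))  # 8-bp deletion
        pair = design_flanking_primers(ref, site)
        assert len(pair.expected_products) == 2
        assert max(pair.expected_products) - min(pair.expected_products) == 8
        h0, h1 = haplotype_templates(ref, [site], [1], (100, 320))
        lengths = sorted(p.length_bp for p in insilico_pcr(pair, [h0, h1]))
        assert lengths == sorted(pair.expected_products)


class TestCallSex:
    def _products(self, lengths):
        return [AssayProduct(l, 0, "p") for l in lengths]

    @pytest.mark.parametrize(
        "lengths,expected",
        [([142, 149], CallValue.MALE), ([149], CallValue.FEMALE), ([], CallValue.UNDETERMINED)],
    )
    def test_size_rule(self, lengths, expected):
        rule = AssayRule(AssayKind.SIZE_DIMORPHISM)
        assert call_sex(self._products(lengths), rule).call == expected

    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([113, 268], CallValue.MALE),
            ([268], CallValue.FEMALE),
            ([], CallValue.UNDETERMINED),
            ([113], CallValue.UNDETERMINED),  # control failure trumps target
        ],
    )
    def test_presence_rule(self, lengths, expected):
        rule = AssayRule(AssayKind.PRESENCE, control_product_bp=268)
        assert call_sex(self._products(lengths), rule).call == expected

    def test_presence_rule_requires_control(self):
        with pytest.raises(ValueError):
            AssayRule(AssayKind.PRESENCE)


class TestAccuracy:
    def test_half_correct(self):
        from sexscan.assay import SexCall

        calls = [
            SexCall("a", CallValue.MALE),
            SexCall("b", CallValue.FEMALE),
            SexCall("c", CallValue.MALE),
            SexCall("d", CallValue.UNDETERMINED),
        ]
        truth = {"a": Sex.MALE, "b": Sex.MALE, "c": Sex.MALE, "d": Sex.MALE}
        rep = assay_accuracy(calls, truth)
        assert rep.accuracy == 0.5
        assert rep.per_sex == {"male": 0.5}

    def test_unknown_sample_errors(self):
        from sexscan.assay import SexCall

        with pytest.raises(KeyError):
            assay_accuracy([SexCall("ghost", CallValue.MALE)], {})

    def test_error_free_size_assay_is_perfect(self, small_cohort):
        """Strictly segregating het indel, no errors: accuracy exactly 1."""
        from sexscan.io import VariantClass, filter_biallelic
        from sexscan.assay import run_assay

        _, cohort = small_cohort
        matrix = filter_biallelic(cohort.matrix, {VariantClass.SNP, VariantClass.INDEL})
        indel = next(
            s for s in matrix.sites if s.variant_class == VariantClass.INDEL
        )
        pair = design_flanking_primers(cohort.reference[indel.scaffold], indel)
        rule = AssayRule(AssayKind.SIZE_DIMORPHISM)
        calls = run_assay(
            matrix,
            cohort.reference,
            pair,
            rule,
            indel.scaffold,
            (indel.position - 200, indel.position + 200),
        )
        rep = assay_accuracy(calls, cohort.truth.sample_sex)
        assert rep.accuracy == 1.0

    def test_accuracy_tracks_error_rate(self):
        """With per-call error e at the target, accuracy ~ 1 - e."""
        from sexscan.simulate import CohortConfig, SDRegionConfig, simulate_cohort
        from sexscan.io import VariantClass, filter_biallelic
        from sexscan.assay import run_assay

        e = 0.1
        n_wrong = 0
        n_total = 0
        for seed in range(25):
            cfg = CohortConfig(
                n_background_sites=0,
                scaffolds=(("scaffold_003", 50_000),),
                sd_region=SDRegionConfig(
                    scaffold="scaffold_003", start=10_000, n_core_sites=1,
                    n_flank_sites=0,
                ),
                missing_rate=0.0,
                error_rate=e,
                seed=seed,
            )
            cohort = simulate_cohort(cfg)
            matrix = filter_biallelic(
                cohort.matrix, {VariantClass.SNP, VariantClass.INDEL}
            )
            indel = matrix.sites[0]
            assert indel.variant_class == VariantClass.INDEL
            pair = design_flanking_primers(cohort.reference[indel.scaffold], indel)
            calls = run_assay(
                matrix,
                cohort.reference,
                pair,
                AssayRule(AssayKind.SIZE_DIMORPHISM),
                indel.scaffold,
                (indel.position - 200, indel.position + 200),
            )
            rep = assay_accuracy(calls, cohort.truth.sample_sex)
            n_total += rep.n_total
            n_wrong += rep.n_total - rep.n_correct
        # per-call wrong probability: e for a het male (either wrong class
        # collapses the double band), e/2 for a hom female (only the flip
        # to het fakes a double band; hom_ref -> hom_alt still shows one)
        p_wrong = e * (15 + 16 / 2) / 31
        p_hat = n_wrong / n_total
        sigma = (p_wrong * (1 - p_wrong) / n_total) ** 0.5
        assert abs(p_hat - p_wrong) < 4 * sigma
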