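"""Two-locus EM, pairwise D'/r2/LOD/CI, and block partitioning."""

import numpy as np
import pytest

from sexscan.io import MISSING
from sexscan.ld import (
    LDConfig,
    PairClass,
    block_span,
    em_haplotype_frequencies,
    gabriel_blocks,
    ld_for_pair,
    pairwise_ld,
)

from conftest import make_matrix, make_samples


def _freqs(calls_i, calls_j):
    return em_haplotype_frequencies(np.array(calls_i), np.array(calls_j))


class TestEM:
    def test_perfect_coupling_no_phase_ambiguity(self):
        """16 hom_ref/hom_ref + 15 het/het: haplotypes are AB and ab only."""
        ci = [0] * 16 + [1] * 15
        f = _freqs(ci, ci)
        assert f.informative
        assert f.p_AB == pytest.approx(47 / 62, abs=1e-6)
        assert f.p_ab == pytest.approx(15 / 62, abs=1e-6)
        assert f.p_Ab == pytest.approx(0.0, abs=1e-6)
        assert f.p_aB == pytest.approx(0.0, abs=1e-6)

    def test_sums_to_one_and_marginals_match(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ci = rng.integers(0, 3, 40)
            cj = rng.integers(0, 3, 40)
            f = _freqs(ci, cj)
            if not f.informative:
                continue
            assert f.vector.sum() == pytest.approx(1.0, abs=1e-9)
            assert f.p_A == pytest.approx(1 - ci.mean() / 2, abs=1e-6)
            assert f.p_B == pytest.approx(1 - cj.mean() / 2, abs=1e-6)

    def test_monomorphic_flagged_uninformative(self):
        f = _freqs([0] * 10, [0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        assert not f.informative

    def test_against_phased_count_oracle(self):
        """EM from genotypes recovers true phased haplotype frequencies."""
        rng = np.random.default_rng(3)
        true_p = np.array([0.45, 0.05, 0.15, 0.35])
        n = 500
        haps = rng.choice(4, size=(n, 2), p=true_p)
        alt_i = np.isin(haps, [2, 3]).sum(axis=1)  # haplotypes aB, ab carry alt at i
        alt_j = np.isin(haps, [1, 3]).sum(axis=1)
        f = _freqs(alt_i, alt_j)
        phased_counts = np.bincount(haps.ravel(), minlength=4) / (2 * n)
        assert np.abs(f.vector - phased_counts).max() < 0.02

    def test_missing_calls_excluded(self):
        ci = [0, 1, MISSING, 2]
        cj = [0, 1, 0, MISSING]
        f = _freqs(ci, cj)
        assert f.n_informative == 2


class TestPairwiseLD:
    def test_zero_cell_gives_dprime_one(self):
        ci = [0] * 16 + [1] * 15
        ld = pairwise_ld(_freqs(ci, ci))
        assert ld.d_prime == pytest.approx(1.0, abs=1e-6)
        assert ld.r2 == pytest.approx(1.0, abs=1e-4)
        assert ld.lod > 2

    def test_independence_zeroes_everything(self):
        # gi == gj never: construct independence exactly via outer structure
        ci = [0, 0, 1, 1, 2, 2, 0, 1, 2] * 4
        cj = [0, 1, 2, 0, 1, 2, 2, 0, 1] * 4
        f = _freqs(ci, cj)
        if abs(f.p_AB - f.p_A * f.p_B) < 1e-9:
            ld = pairwise_ld(f)
            assert ld.r2 == pytest.approx(0.0, abs=1e-9)
            assert ld.lod == pytest.approx(0.0, abs=1e-9)

    def test_ci_bounds_ordered_and_near_mle(self):
        """Bounds are ordered in [0, 1] and bracket the MLE up to the mass
        resolution of the grid quantiles (a boundary MLE can overshoot the
        95th-percentile bound by a little, never by much on decent data)."""
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(30):
            ci = rng.integers(0, 3, 50)
            cj = np.where(rng.random(50) < 0.7, ci, rng.integers(0, 3, 50))
            f = _freqs(ci, cj)
            if not f.informative:
                continue
            ld = pairwise_ld(f)
            assert 0 <= ld.ci_low <= ld.ci_high <= 1
            assert ld.ci_low - 0.05 <= ld.d_prime <= ld.ci_high + 0.05
            checked += 1
        assert checked > 10

    def test_perfect_ld_pair_is_strong(self):
        """A perfectly coupled pair satisfies the strong-LD bound rule."""
        calls = [0] * 16 + [1] * 15
        ld = pairwise_ld(_freqs(calls, calls))
        assert ld.ci_low >= 0.70 and ld.ci_high >= 0.98
        assert ld.pair_class == PairClass.STRONG_LD

    def test_ci_stable_against_finer_grid(self):
        """Bounds at step 1e-3 within one coarse step of a 10x finer grid."""
        ci = [0] * 10 + [1] * 12 + [2] * 9
        cj = [0] * 10 + [1] * 10 + [0, 2] + [2] * 9
        f = _freqs(ci, cj)
        coarse = pairwise_ld(f, LDConfig(dprime_grid_step=0.001))
        fine = pairwise_ld(f, LDConfig(dprime_grid_step=0.0001))
        assert abs(coarse.ci_low - fine.ci_low) <= 0.001 + 1e-9
        assert abs(coarse.ci_high - fine.ci_high) <= 0.001 + 1e-9

    def test_uninformative_class(self):
        f = _freqs([0] * 10, [0, 1] * 5)
        assert pairwise_ld(f).pair_class == PairClass.UNINFORMATIVE


class TestBlockSpan:
    @pytest.mark.parametrize(
        "first,last,expected",
        [
            (3723703, 3726876, 3174),
            (13757866, 13758271, 406),
            (620689, 620873, 185),
            (56072, 57275, 1204),
            (5, 5, 1),
        ],
    )
    def test_inclusive_span(self, first, last, expected):
        assert block_span(first, last) == expected

    def test_reversed_bounds_error(self):
        with pytest.raises(ValueError):
            block_span(10, 9)


class TestGabrielBlocks:
    def _linked_cluster_matrix(self, cluster_starts, n_per_cluster=5, spacing=100):
        """Clusters of perfectly coupled markers separated by equilibrium
        markers, on a 31-sample cohort."""
        rng = np.random.default_rng(17)
        samples = make_samples(16, 15)
        linked = [0] * 16 + [1] * 15
        specs = []
        for start in cluster_starts:
            for k in range(n_per_cluster):
                specs.append(("sc", start + k * spacing, "A", ["T"], list(linked)))
        # independent common markers between clusters
        for pos in range(25_000, 26_000, 200):
            calls = list(rng.integers(0, 3, 31))
            specs.append(("sc", pos, "C", ["G"], calls))
        specs.sort(key=lambda s: s[1])
        return make_matrix(specs, samples)

    def test_single_cluster_single_block(self):
        m = self._linked_cluster_matrix([10_000])
        blocks = gabriel_blocks(m, "sc")
        assert len(blocks) >= 1
        top = max(blocks, key=lambda b: b.span_bp)
        assert top.first_pos == 10_000 and top.last_pos == 10_400
        assert top.n_markers == 5

    def test_two_clusters_two_blocks(self):
        m = self._linked_cluster_matrix([10_000, 50_000])
        blocks = gabriel_blocks(m, "sc")
        spans = sorted((b.first_pos, b.last_pos) for b in blocks if b.n_markers >= 5)
        assert (10_000, 10_400) in spans
        assert (50_000, 50_400) in spans

    def test_blocks_do_not_overlap(self):
        m = self._linked_cluster_matrix([10_000, 50_000])
        blocks = sorted(gabriel_blocks(m, "sc"), key=lambda b: b.first_pos)
        for a, b in zip(blocks, blocks[1:]):
            assert a.last_pos < b.first_pos

    def test_single_marker_no_blocks(self):
        samples = make_samples(16, 15)
        m = make_matrix(
            [("sc", 100, "A", ["T"], [0] * 16 + [1] * 15)], samples
        )
        assert gabriel_blocks(m, "sc") == []

    def test_core_pairs_all_dprime_one(self, small_cohort):
        """Recombination-suppressed core at error 0: every pair has D' = 1."""
        _, cohort = small_cohort
        matrix = cohort.matrix
        core = [
            i
            for i, s in enumerate(matrix.sites)
            if cohort.truth.class_of(s.scaffold, s.position) == "core"
        ]
        for i, j in zip(core[:-1], core[1:]):
            ld = ld_for_pair(matrix, i, j)
            assert ld.d_prime == pytest.approx(1.0, abs=1e-6)
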