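"""Pairwise linkage disequilibrium from unphased genotypes and
confidence-interval LD-block partitioning.

Haplotype frequencies for a site pair are estimated by the standard
two-locus EM over the double-heterozygote phase ambiguity; D, D', r2 and a
LOD score follow.  Confidence bounds on D' come from the genotype
likelihood evaluated on a D' grid with allele frequencies profiled at
their MLE — the approach of the classic block-finding programs.  Blocks
use the confidence-interval rule: an interval whose endpoint pair is in
"strong LD" (CI lower bound >= 0.70, upper >= 0.98) and in which at least
95% of informative pairs are strong, taken greedily by bp span.

All defaults are exposed in :class:`LDConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


class PairClass(str, Enum):
    STRONG_LD = "strong_ld"
    STRONG_RECOMBINATION = "strong_recombination"
    OTHER = "other"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class LDConfig:
    """Thresholds of the confidence-interval block method (program defaults)."""

    strong_ld_low: float = 0.70
    strong_ld_high: float = 0.98
    recomb_high: float = 0.90
    min_strong_fraction: float = 0.95
    ci_mass: float = 0.90  # two-sided
    dprime_grid_step: float = 0.001
    min_maf: float = 0.05
    max_pair_distance_bp: int = 500_000
    em_tol: float = 1e-10
    em_max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.strong_ld_low < self.strong_ld_high <= 1:
            raise ValueError("need 0 < strong_ld_low < strong_ld_high <= 1")
        if not 0 < self.recomb_high < self.strong_ld_high:
            raise ValueError("need 0 < recomb_high < strong_ld_high")


@dataclass
class HaplotypeFreqs:
    """ML two-locus haplotype frequencies (A/B = reference alleles).

    ``counts`` keeps the 3x3 genotype-pair table the likelihood-based
    statistics (LOD, D' confidence bounds) are computed from.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    n_informative: int
    counts: np.ndarray | None = None
    informative: bool = True

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB


@dataclass
class PairwiseLD:
    D: float
    d_prime: float
    r2: float
    lod: float
    ci_low: float
    ci_high: float
    pair_class: PairClass


@dataclass
class LDBlock:
    scaffold: str
    first_pos: int
    last_pos: int
    member_sites: list[int]  # site indices into the source matrix

    @property
    def span_bp(self) -> int:
        return block_span(self.first_pos, self.last_pos)

    @property
    def n_markers(self) -> int:
        return len(self.member_sites)


def block_span(first_pos: int, last_pos: int) -> int:
    """Inclusive bp span, 1-based: last - first + 1."""
    if last_pos < first_pos:
        raise ValueError(f"last_pos {last_pos} < first_pos {first_pos}")
    return last_pos - first_pos + 1


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

# haplotypes ordered AB, Ab, aB, ab; entry = count of alt alleles at (i, j)
_HAP_ALT_I = np.array([0, 0, 1, 1])
_HAP_ALT_J = np.array([0, 1, 0, 1])


def _pair_counts(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[np.ndarray, int]:
    mask = (calls_i != MISSING) & (calls_j != MISSING)
    counts = np.zeros((3, 3))
    np.add.at(counts, (calls_i[mask], calls_j[mask]), 1.0)
    return counts, int(mask.sum())


# fixed haplotype contributions of each genotype-pair cell except the
# double het: cell (gi, gj) with c samples contributes 2c haplotypes whose
# phase is determined.
_FIXED = np.zeros((3, 3, 4))
for gi in range(3):
    for gj in range(3):
        if gi == 1 and gj == 1:
            continue
        if gi == 1:
            pairs = [(0, gj // 2), (1, gj // 2)]  # one A-hap, one a-hap
        elif gj == 1:
            pairs = [(gi // 2, 0), (gi // 2, 1)]
        else:
            pairs = [(gi // 2, gj // 2)] * 2
        for ai, aj in pairs:
            _FIXED[gi, gj, 2 * ai + aj] += 1.0
del gi, gj, pairs, ai, aj


def em_haplotype_frequencies(
    calls_i: np.ndarray,
    calls_j: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """ML haplotype frequencies for a site pair by EM over phase ambiguity.

    Initialised at linkage equilibrium (products of allele frequencies);
    iterated until the largest frequency change is below ``tol``.  A pair
    monomorphic among the shared genotyped samples is flagged
    uninformative, not an error.
    """
    calls_i = np.asarray(calls_i)
    calls_j = np.asarray(calls_j)
    counts, n = _pair_counts(calls_i, calls_j)
    if n < 2:
        return HaplotypeFreqs(0, 0, 0, 0, n, counts, informative=False)
    tot = 2.0 * n
    alt_i = float((counts * np.arange(3)[:, None]).sum()) / tot
    alt_j = float((counts * np.arange(3)[None, :]).sum()) / tot
    pA, pB = 1.0 - alt_i, 1.0 - alt_j
    if min(pA, 1 - pA) == 0.0 or min(pB, 1 - pB) == 0.0:
        return HaplotypeFreqs(
            pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB),
            n, counts, informative=False,
        )

    base = np.tensordot(counts, _FIXED, axes=([0, 1], [0, 1]))
    n_dh = counts[1, 1]
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    for _ in range(max_iter):
        coupling = p[0] * p[3]
        repulsion = p[1] * p[2]
        denom = coupling + repulsion
        x = n_dh * (coupling / denom) if denom > 0 else n_dh * 0.5
        hap = base + np.array([x, n_dh - x, n_dh - x, x])
        p_new = hap / tot
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return HaplotypeFreqs(*(float(v) for v in p), n, counts, informative=True)


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------


# map an unordered haplotype pair (h, k) to its 3x3 genotype cell, as a
# (4, 4, 9) indicator used to turn haplotype frequencies into genotype
# probabilities in one contraction
_PAIR_TO_CELL = np.zeros((4, 4, 9))
for _h in range(4):
    for _k in range(4):
        _gi = _HAP_ALT_I[_h] + _HAP_ALT_I[_k]
        _gj = _HAP_ALT_J[_h] + _HAP_ALT_J[_k]
        _PAIR_TO_CELL[_h, _k, 3 * _gi + _gj] = 1.0
del _h, _k, _gi, _gj


def _genotype_probs(p: np.ndarray) -> np.ndarray:
    """Genotype-pair probabilities from haplotype frequencies.

    ``p`` may be a single 4-vector or a (G, 4) stack; returns 3x3 or
    (G, 9) correspondingly.
    """
    if p.ndim == 1:
        return np.einsum("h,k,hkc->c", p, p, _PAIR_TO_CELL).reshape(3, 3)
    return np.einsum("gh,gk,hkc->gc", p, p, _PAIR_TO_CELL)


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    probs = np.clip(_genotype_probs(p), 1e-300, None)
    return float((counts * np.log(probs)).sum())


def _hap_vector(pA: float, pB: float, D: float) -> np.ndarray:
    v = np.array(
        [
            pA * pB + D,
            pA * (1 - pB) - D,
            (1 - pA) * pB - D,
            (1 - pA) * (1 - pB) + D,
        ]
    )
    return np.clip(v, 0.0, 1.0)


def _d_max(pA: float, pB: float, sign: int) -> float:
    if sign >= 0:
        return min(pA * (1 - pB), (1 - pA) * pB)
    return min(pA * pB, (1 - pA) * (1 - pB))


def pairwise_ld(freqs: HaplotypeFreqs, config: LDConfig | None = None) -> PairwiseLD:
    """D, D', r2, LOD and D'-confidence bounds for one site pair.

    Uninformative frequencies yield ``pair_class = uninformative`` with
    zeroed statistics.
    """
    config = config or LDConfig()
    if not freqs.informative:
        return PairwiseLD(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, PairClass.UNINFORMATIVE)
    pA, pB = freqs.p_A, freqs.p_B
    D = freqs.p_AB - pA * pB
    sign = 1 if D >= 0 else -1
    d_max = _d_max(pA, pB, sign)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    d_prime = min(d_prime, 1.0)
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = (D * D) / denom if denom > 0 else 0.0

    counts = freqs.counts
    ll_mle = _loglik(counts, freqs.vector)
    ll_null = _loglik(counts, _hap_vector(pA, pB, 0.0))
    lod = (ll_mle - ll_null) / _LN10
    if abs(D) < 1e-12:
        lod = 0.0

    # D' grid likelihood, allele frequencies fixed at MLE, sign at MLE sign
    grid = np.arange(0.0, 1.0 + config.dprime_grid_step / 2, config.dprime_grid_step)
    Dd = sign * grid * d_max
    hap_stack = np.clip(
        np.stack(
            [
                pA * pB + Dd,
                pA * (1 - pB) - Dd,
                (1 - pA) * pB - Dd,
                (1 - pA) * (1 - pB) + Dd,
            ],
            axis=1,
        ),
        0.0,
        1.0,
    )
    probs = np.clip(_genotype_probs(hap_stack), 1e-300, None)
    lls = np.log(probs) @ counts.reshape(9)
    w = np.exp(lls - lls.max())
    total = w.sum()
    tail = (1.0 - config.ci_mass) / 2.0
    cdf = np.cumsum(w) / total
    upper = np.cumsum(w[::-1])[::-1] / total  # mass at or above each grid point
    low_idx = int(np.argmax(cdf > tail))
    high_candidates = np.nonzero(upper > tail)[0]
    high_idx = int(high_candidates[-1]) if len(high_candidates) else len(grid) - 1
    ci_low = float(grid[low_idx])
    ci_high = float(grid[high_idx])

    if ci_low >= config.strong_ld_low and ci_high >= config.strong_ld_high:
        pair_class = PairClass.STRONG_LD
    elif ci_high < config.recomb_high:
        pair_class = PairClass.STRONG_RECOMBINATION
    else:
        pair_class = PairClass.OTHER
    return PairwiseLD(float(D), float(d_prime), float(r2), float(lod), ci_low, ci_high, pair_class)


def ld_for_pair(
    matrix: GenotypeMatrix, i: int, j: int, config: LDConfig | None = None
) -> PairwiseLD:
    """Convenience: EM + pairwise statistics for two site indices."""
    freqs = em_haplotype_frequencies(matrix.calls[i], matrix.calls[j])
    return pairwise_ld(freqs, config)


# ---------------------------------------------------------------------------
# block partitioning
# ---------------------------------------------------------------------------


def _eligible_markers(
    matrix: GenotypeMatrix,
    scaffold: str,
    config: LDConfig,
    window: tuple[int, int] | None,
) -> np.ndarray:
    idx = matrix.scaffold_site_indices(scaffold, window)
    keep = []
    for i in idx:
        row = matrix.calls[i]
        called = row[row != MISSING]
        if len(called) < 2:
            continue
        alt_freq = float((called).sum()) / (2 * len(called))
        maf = min(alt_freq, 1 - alt_freq)
        if maf < config.min_maf:
            continue
        keep.append(i)
    return np.array(keep, dtype=int)


def pairwise_ld_table(
    matrix: GenotypeMatrix,
    site_indices: Sequence[int],
    config: LDConfig | None = None,
) -> list[tuple[int, int, PairwiseLD]]:
    """All pairwise LD results among the given sites (within max distance)."""
    config = config or LDConfig()
    out = []
    idx = list(site_indices)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if (
                abs(matrix.sites[j].position - matrix.sites[i].position)
                > config.max_pair_distance_bp
            ):
                out.append((i, j, PairwiseLD(0, 0, 0, 0, 0, 0, PairClass.UNINFORMATIVE)))
                continue
            out.append((i, j, ld_for_pair(matrix, i, j, config)))
    return out


def gabriel_blocks(
    matrix: GenotypeMatrix,
    scaffold: str,
    config: LDConfig | None = None,
    window: tuple[int, int] | None = None,
) -> list[LDBlock]:
    """Confidence-interval LD blocks on one scaffold.

    Candidate blocks are marker intervals whose endpoint pair is strong-LD
    and in which at least ``min_strong_fraction`` of informative pairs
    (strong-LD or strong-recombination) are strong-LD.  Candidates are
    sorted by bp span descending (ties: more markers, then smaller start)
    and accepted greedily if they do not overlap an accepted block.
    """
    config = config or LDConfig()
    markers = _eligible_markers(matrix, scaffold, config, window)
    m = len(markers)
    if m < 2:
        return []
    positions = np.array([matrix.sites[i].position for i in markers])

    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for a in range(m):
        for b in range(a + 1, m):
            if positions[b] - positions[a] > config.max_pair_distance_bp:
                continue
            ld = ld_for_pair(matrix, markers[a], markers[b], config)
            if ld.pair_class == PairClass.STRONG_LD:
                strong[a, b] = True
                informative[a, b] = True
            elif ld.pair_class == PairClass.STRONG_RECOMBINATION:
                informative[a, b] = True

    # integral images for O(1) interval pair counts
    s_cum = strong.astype(int).cumsum(0).cumsum(1)
    i_cum = informative.astype(int).cumsum(0).cumsum(1)

    def region_sum(cum: np.ndarray, a: int, b: int) -> int:
        total = cum[b, b]
        if a > 0:
            total -= cum[a - 1, b] + cum[b, a - 1] - cum[a - 1, a - 1]
        return int(total)

    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            if not strong[a, b]:
                continue
            n_inf = region_sum(i_cum, a, b)
            n_str = region_sum(s_cum, a, b)
            if n_inf == 0 or n_str / n_inf < config.min_strong_fraction:
                continue
            span = block_span(int(positions[a]), int(positions[b]))
            candidates.append((span, b - a + 1, int(positions[a]), a, b))

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    blocks: list[LDBlock] = []
    taken: list[tuple[int, int]] = []
    for span, n_mark, start, a, b in candidates:
        lo, hi = int(positions[a]), int(positions[b])
        if any(not (hi < t_lo or lo > t_hi) for t_lo, t_hi in taken):
            continue
        taken.append((lo, hi))
        blocks.append(
            LDBlock(
                scaffold=scaffold,
                first_pos=lo,
                last_pos=hi,
                member_sites=[int(markers[k]) for k in range(a, b + 1)],
            )
        )
    blocks.sort(key=lambda blk: blk.first_pos)
    logger.info(
        "gabriel_blocks %s: %d eligible markers, %d blocks (largest %d bp)",
        scaffold,
        m,
        len(blocks),
        max((blk.span_bp for blk in blocks), default=0),
    )
    return blocks
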