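"""Exact contingency-table tests used by the sex-linkage scan.

Two primitives, both computed in log-factorial space and cached by table
(identical tables recur massively across a genome scan):

* :func:`fisher_exact_2x3` — the two-sided Fisher exact test on a
  2 (sex) x 3 (genotype class) table, by full enumeration of tables with
  the observed margins under the multivariate hypergeometric null.
* :func:`hwe_exact_p` — the standard exact Hardy-Weinberg test
  conditioning on allele counts.

Two-sidedness follows the conventional definition: sum the null
probabilities of every table whose probability is <= that of the observed
table, within relative tolerance 1e-7 to absorb floating error in the
log-space sums.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

_REL_TOL = 1e-7
_LOG_TOL = math.log1p(_REL_TOL)


def _logfact(n):
    return gammaln(np.asarray(n, dtype=float) + 1.0)


@lru_cache(maxsize=1 << 20)
def _fisher_2x3_cached(row1: tuple[int, int, int], row2: tuple[int, int, int]) -> float:
    r1, r2 = sum(row1), sum(row2)
    if r1 == 0 or r2 == 0:
        raise ValueError("empty sex stratum in 2x3 table")
    cols = tuple(a + b for a, b in zip(row1, row2))
    n = r1 + r2

    # enumerate top rows (a, b, r1-a-b) consistent with the margins
    a_max = min(r1, cols[0])
    a = np.arange(0, a_max + 1)
    grids = []
    for ai in a:
        b_lo = max(0, r1 - ai - cols[2])
        b_hi = min(r1 - ai, cols[1])
        if b_hi < b_lo:
            continue
        b = np.arange(b_lo, b_hi + 1)
        grids.append(np.column_stack([np.full_like(b, ai), b]))
    ab = np.concatenate(grids, axis=0)
    top = np.column_stack([ab[:, 0], ab[:, 1], r1 - ab[:, 0] - ab[:, 1]])
    bot = np.array(cols)[None, :] - top

    const = (
        _logfact(r1)
        + _logfact(r2)
        + sum(_logfact(c) for c in cols)
        - _logfact(n)
    )
    logp = const - _logfact(top).sum(axis=1) - _logfact(bot).sum(axis=1)

    obs = np.array(row1)
    logp_obs = const - _logfact(obs).sum() - _logfact(np.array(cols) - obs).sum()

    p = float(np.exp(logp[logp <= logp_obs + _LOG_TOL]).sum())
    return min(p, 1.0)


def fisher_exact_2x3(table) -> float:
    """Two-sided exact p for a 2x3 genotype-by-sex table.

    ``table`` is anything exposing ``female_counts``/``male_counts`` or a
    pair of 3-tuples ``((f0, f1, f2), (m0, m1, m2))``.  Raises ValueError
    if either sex stratum is empty.
    """
    if hasattr(table, "female_counts"):
        row1, row2 = tuple(table.female_counts), tuple(table.male_counts)
    else:
        row1, row2 = tuple(table[0]), tuple(table[1])
    return _fisher_2x3_cached(tuple(int(x) for x in row1), tuple(int(x) for x in row2))


@lru_cache(maxsize=1 << 18)
def _hwe_cached(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("HWE test needs at least one genotyped sample")
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic

    # heterozygote counts share the parity of min(n_a, n_b)
    k_max = min(n_a, n_b)
    k = np.arange(k_max % 2, k_max + 1, 2)
    const = (
        _logfact(n) + _logfact(n_a) + _logfact(n_b) - _logfact(2 * n)
    )
    logp = (
        const
        + k * math.log(2.0)
        - _logfact((n_a - k) // 2)
        - _logfact(k)
        - _logfact((n_b - k) // 2)
    )
    logp_obs = logp[k == n_het][0]
    p = float(np.exp(logp[logp <= logp_obs + _LOG_TOL]).sum())
    return min(p, 1.0)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg p conditioning on the observed allele counts.

    Sums the probabilities of heterozygote counts (same parity, fixed
    allele totals) whose conditional probability is <= the observed
    configuration's.  Monomorphic input returns 1.0.
    """
    return _hwe_cached(int(n_hom_ref), int(n_het), int(n_hom_alt))
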