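import numpy as np
import pytest

from sexscan.io import GenotypeMatrix, Sex, SexedSample, VariantSite


def make_samples(n_females: int, n_males: int, n_unknown: int = 0):
    return (
        [SexedSample(f"F{i}", Sex.FEMALE) for i in range(n_females)]
        + [SexedSample(f"M{i}", Sex.MALE) for i in range(n_males)]
        + [SexedSample(f"U{i}", Sex.UNKNOWN) for i in range(n_unknown)]
    )


def make_matrix(site_specs, samples):
    """site_specs: list of (scaffold, pos, ref, alts, calls-list)."""
    sites = [VariantSite(sc, pos, ref, tuple(alts)) for sc, pos, ref, alts, _ in site_specs]
    calls = np.array([row for *_, row in site_specs], dtype=np.int8)
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


def strict_site_calls(n_females: int, n_males: int, het_sex="male"):
    """Calls for a strictly segregating site (F block first, then M)."""
    if het_sex == "male":
        return [0] * n_females + [1] * n_males
    return [1] * n_females + [0] * n_males


@pytest.fixture(scope="session")
def small_cohort():
    """Small error-free simulated cohort shared across tests."""
    from sexscan.simulate import CohortConfig, SDRegionConfig, simulate_cohort

    cfg = CohortConfig(
        n_background_sites=300,
        scaffolds=(("scaffold_001", 200_000), ("scaffold_003", 200_000)),
        sd_region=SDRegionConfig(scaffold="scaffold_003", start=100_000),
        missing_rate=0.0,
        error_rate=0.0,
        seed=42,
    )
    return cfg, simulate_cohort(cfg)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the package's log-space path)
# ---------------------------------------------------------------------------


def fisher_2x3_oracle(row1, row2):
    """Direct-probability enumeration of all 2x3 tables with the margins."""
    from math import comb

    r1 = sum(row1)
    cols = [a + b for a, b in zip(row1, row2)]
    n = r1 + sum(row2)

    def table_prob(top):
        # P(top | margins) = prod_c C(col_c, top_c) / C(n, r1)
        num = 1
        for c, t in zip(cols, top):
            num *= comb(c, t)
        return num / comb(n, r1)

    p_obs = table_prob(row1)
    total = 0.0
    for a in range(0, min(r1, cols[0]) + 1):
        for b in range(0, min(r1 - a, cols[1]) + 1):
            c = r1 - a - b
            if c > cols[2]:
                continue
            p = table_prob((a, b, c))
            if p <= p_obs * (1 + 1e-7):
                total += p
    return min(total, 1.0)


def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Direct enumeration over heterozygote counts with fixed allele totals."""
    from math import comb, factorial

    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0

    def prob(k):
        naa = (n_a - k) // 2
        nbb = (n_b - k) // 2
        return (
            factorial(n)
            / (factorial(naa) * factorial(k) * factorial(nbb))
            * 2**k
            * factorial(n_a)
            * factorial(n_b)
            / factorial(2 * n)
        )

    p_obs = prob(n_het)
    total = 0.0
    for k in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2):
        p = prob(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)
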