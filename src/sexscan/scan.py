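"""Genome-wide sex-linkage scan.

The scan asks, per variant site, whether genotype is associated with
phenotypic sex (exact 2x3 Fisher test at a fixed genome-wide threshold,
default 5e-8), whether the site survives a Hardy-Weinberg exact filter in
the configured stratum, and whether it shows *strict sex-specific
segregation*: every genotyped individual of one sex heterozygous and every
genotyped individual of the other sex in one single homozygous class.  A
site is reported sex-specific iff it is significant and strictly
segregating; the heterogametic system (XY vs ZW) follows from which sex
carries the heterozygotes.

Shaped like a statsmodels model: build :class:`SexLinkageModel` from a
:class:`~sexscan.io.GenotypeMatrix` (or a VCF + sex map), call
:meth:`~SexLinkageModel.fit`, and work with the returned
:class:`ScanResults` (per-site estimates, ``summary()``, Manhattan and
report exports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exact import fisher_exact_2x3, hwe_exact_p
from .io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    Sex,
    SexedSample,
    VariantClass,
    VariantSite,
    filter_biallelic,
    read_sex_map,
    read_vcf,
)

logger = logging.getLogger(__name__)


class SegregationClass(str, Enum):
    MALE_HET = "male_het"
    FEMALE_HET = "female_het"
    NONE = "none"


@dataclass(frozen=True)
class ScanConfig:
    """Scan thresholds.

    alpha
        Genome-wide significance threshold on the exact p (strict
        inequality ``p < alpha``).
    hwe_threshold
        Sites with Hardy-Weinberg exact p below this are filtered out.
    hwe_scope
        Stratum the HWE filter is computed in.  Default ``females_only``:
        in a male-heterogametic system the homogametic sex is the natural
        control stratum, and an all-heterozygous male stratum must not
        disqualify a true sex-linked site.
    min_call_fraction_per_sex
        Both sexes must be genotyped at at least this fraction of their
        samples for a site to be significant or classified.
    """

    alpha: float = 5e-8
    hwe_threshold: float = 1e-4
    hwe_scope: str = "females_only"  # females_only | males_only | all_samples | none
    min_call_fraction_per_sex: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.hwe_threshold < 1.0:
            raise ValueError("hwe_threshold must be in [0, 1)")
        if not 0.0 < self.min_call_fraction_per_sex <= 1.0:
            raise ValueError("min_call_fraction_per_sex must be in (0, 1]")
        if self.hwe_scope not in {"females_only", "males_only", "all_samples", "none"}:
            raise ValueError(f"unknown hwe_scope {self.hwe_scope!r}")


@dataclass(frozen=True)
class SexGenotypeTable:
    """Per-site 2x3 counts: (hom_ref, het, hom_alt) per sex.

    ``n_females_total`` / ``n_males_total`` carry the cohort sizes so call
    fractions can be checked; missing calls are excluded from the counts.
    """

    female_counts: tuple[int, int, int]
    male_counts: tuple[int, int, int]
    n_females_total: int = 0
    n_males_total: int = 0

    @property
    def n_females_called(self) -> int:
        return sum(self.female_counts)

    @property
    def n_males_called(self) -> int:
        return sum(self.male_counts)

    def call_fractions(self) -> tuple[float, float]:
        f = self.n_females_called / self.n_females_total if self.n_females_total else 0.0
        m = self.n_males_called / self.n_males_total if self.n_males_total else 0.0
        return f, m

    def swapped(self) -> "SexGenotypeTable":
        return SexGenotypeTable(
            self.male_counts, self.female_counts, self.n_males_total, self.n_females_total
        )


@dataclass
class SiteAssociation:
    """Per-site scan result."""

    site: VariantSite
    table: SexGenotypeTable
    fisher_p: float
    hwe_p: float
    segregation: SegregationClass
    significant: bool

    @property
    def sex_specific(self) -> bool:
        return self.significant and self.segregation != SegregationClass.NONE

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.fisher_p)) if self.fisher_p > 0 else np.inf


def _count_tuple(calls: np.ndarray) -> tuple[int, int, int]:
    return (
        int(np.count_nonzero(calls == HOM_REF)),
        int(np.count_nonzero(calls == HET)),
        int(np.count_nonzero(calls == HOM_ALT)),
    )


def genotype_table(site_index: int, matrix: GenotypeMatrix) -> SexGenotypeTable:
    """2x3 counts at one site; missing and unknown-sex samples excluded."""
    row = matrix.calls[site_index]
    f_idx = matrix.female_indices
    m_idx = matrix.male_indices
    return SexGenotypeTable(
        female_counts=_count_tuple(row[f_idx]),
        male_counts=_count_tuple(row[m_idx]),
        n_females_total=len(f_idx),
        n_males_total=len(m_idx),
    )


def _strict_het_hom(het_counts, hom_counts) -> bool:
    """het row is (0, k, 0), k>=1; hom row is all in one homozygous class."""
    if het_counts[0] or het_counts[2] or het_counts[1] < 1:
        return False
    hom_total = hom_counts[0] + hom_counts[2]
    if hom_counts[1] or hom_total < 1:
        return False
    return hom_counts[0] == hom_total or hom_counts[2] == hom_total


def classify_segregation(
    table: SexGenotypeTable, config: ScanConfig | None = None
) -> SegregationClass:
    """Strict segregation class of a 2x3 table.

    ``male_het``: every genotyped male het AND every genotyped female in a
    single homozygous class (hom_ref or hom_alt — requiring hom_ref would
    bake in the reference individual's sex).  ``female_het`` is the exact
    mirror.  Both sexes must satisfy the per-sex call-fraction minimum.
    """
    config = config or ScanConfig()
    f_frac, m_frac = table.call_fractions()
    if table.n_females_total and f_frac < config.min_call_fraction_per_sex:
        return SegregationClass.NONE
    if table.n_males_total and m_frac < config.min_call_fraction_per_sex:
        return SegregationClass.NONE
    if _strict_het_hom(table.male_counts, table.female_counts):
        return SegregationClass.MALE_HET
    if _strict_het_hom(table.female_counts, table.male_counts):
        return SegregationClass.FEMALE_HET
    return SegregationClass.NONE


def _hwe_for_scope(table: SexGenotypeTable, scope: str) -> float:
    if scope == "none":
        return 1.0
    if scope == "females_only":
        counts = table.female_counts
    elif scope == "males_only":
        counts = table.male_counts
    else:  # all_samples
        counts = tuple(f + m for f, m in zip(table.female_counts, table.male_counts))
    if sum(counts) == 0:
        return 1.0
    return hwe_exact_p(*counts)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class SexLinkageModel:
    """Exact sex-vs-genotype association model over a genotype matrix.

    Parameters
    ----------
    matrix
        Biallelic genotype matrix (filter with
        :func:`sexscan.io.filter_biallelic` first; the constructor checks).
    config
        :class:`ScanConfig`; defaults are the conventional genome-wide
        settings (alpha 5e-8, HWE filter 1e-4 in females).
    """

    def __init__(self, matrix: GenotypeMatrix, config: ScanConfig | None = None):
        if any(not s.is_biallelic for s in matrix.sites):
            raise ValueError("matrix contains multiallelic sites; filter first")
        if len(matrix.female_indices) == 0 or len(matrix.male_indices) == 0:
            raise ValueError("cohort must contain at least one sample of each sex")
        self.matrix = matrix
        self.config = config or ScanConfig()

    @classmethod
    def from_vcf(
        cls,
        vcf_path: str | Path,
        sex_map_path: str | Path,
        config: ScanConfig | None = None,
        keep_classes: Iterable[VariantClass | str] = (VariantClass.SNP,),
    ) -> "SexLinkageModel":
        samples = read_sex_map(sex_map_path)
        matrix = filter_biallelic(read_vcf(vcf_path, samples), keep_classes)
        return cls(matrix, config)

    def fit(
        self,
        scaffold: str | None = None,
        window: tuple[int, int] | None = None,
    ) -> "ScanResults":
        """Run the scan; optionally restricted to a scaffold (and bp window)."""
        matrix = self.matrix
        cfg = self.config
        if scaffold is not None:
            idx = matrix.scaffold_site_indices(scaffold, window)
            site_indices = idx
        else:
            site_indices = np.arange(matrix.n_sites)

        f_idx, m_idx = matrix.female_indices, matrix.male_indices
        nf, nm = len(f_idx), len(m_idx)
        calls = matrix.calls[site_indices]
        # vectorised 2x3 counts
        fcalls, mcalls = calls[:, f_idx], calls[:, m_idx]
        fc = np.stack([(fcalls == g).sum(axis=1) for g in (HOM_REF, HET, HOM_ALT)], 1)
        mc = np.stack([(mcalls == g).sum(axis=1) for g in (HOM_REF, HET, HOM_ALT)], 1)

        assocs: list[SiteAssociation] = []
        min_frac = cfg.min_call_fraction_per_sex
        for k, i in enumerate(site_indices):
            table = SexGenotypeTable(
                tuple(int(x) for x in fc[k]),
                tuple(int(x) for x in mc[k]),
                nf,
                nm,
            )
            p = fisher_exact_2x3(table)
            hwe = _hwe_for_scope(table, cfg.hwe_scope)
            seg = classify_segregation(table, cfg)
            f_frac, m_frac = table.call_fractions()
            significant = (
                p < cfg.alpha
                and hwe >= cfg.hwe_threshold
                and f_frac >= min_frac
                and m_frac >= min_frac
            )
            assocs.append(
                SiteAssociation(matrix.sites[i], table, p, hwe, seg, significant)
            )
        n_hits = sum(a.sex_specific for a in assocs)
        logger.info(
            "scan: %d sites tested, %d significant sex-specific", len(assocs), n_hits
        )
        return ScanResults(self, assocs)


class ScanResults:
    """Fitted scan: per-site associations plus summaries and exports."""

    def __init__(self, model: SexLinkageModel, associations: list[SiteAssociation]):
        self.model = model
        self.associations = associations

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self):
        return iter(self.associations)

    @property
    def sex_specific(self) -> list[SiteAssociation]:
        return [a for a in self.associations if a.sex_specific]

    @property
    def significant(self) -> list[SiteAssociation]:
        return [a for a in self.associations if a.significant]

    def heterogametic_system(self) -> str:
        """XY / ZW / undetermined, from the majority strict class of hits."""
        hits = self.sex_specific
        n_male = sum(a.segregation == SegregationClass.MALE_HET for a in hits)
        n_female = sum(a.segregation == SegregationClass.FEMALE_HET for a in hits)
        if n_male > n_female:
            return "XY"
        if n_female > n_male:
            return "ZW"
        return "undetermined"

    def frame(self) -> pd.DataFrame:
        """Association table in the catalogue style: counts as 'a/b/c' per sex."""
        rows = []
        for a in self.associations:
            t = a.table
            rows.append(
                {
                    "scaffold": a.site.scaffold,
                    "position": a.site.position,
                    "ref": a.site.ref_allele,
                    "alt": a.site.alt_alleles[0] if a.site.alt_alleles else ".",
                    "females": "/".join(map(str, t.female_counts)),
                    "males": "/".join(map(str, t.male_counts)),
                    "fisher_p": a.fisher_p,
                    "hwe_p": a.hwe_p,
                    "segregation": a.segregation.value,
                    "significant": a.significant,
                    "sex_specific": a.sex_specific,
                }
            )
        return pd.DataFrame(rows)

    def manhattan_frame(self) -> pd.DataFrame:
        """Cumulative position, -log10(p), scaffold index (Manhattan data)."""
        rows = []
        offset = 0
        scaffold_order = self.model.matrix.scaffolds
        spans = {
            sc: max(
                (a.site.position for a in self.associations if a.site.scaffold == sc),
                default=0,
            )
            for sc in scaffold_order
        }
        for idx, sc in enumerate(scaffold_order):
            for a in self.associations:
                if a.site.scaffold != sc:
                    continue
                rows.append(
                    {
                        "scaffold": sc,
                        "scaffold_index": idx,
                        "position": a.site.position,
                        "cumulative_position": offset + a.site.position,
                        "neg_log10_p": a.neg_log10_p,
                        "sex_specific": a.sex_specific,
                    }
                )
            offset += spans[sc]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.config
        hits = self.sex_specific
        scaffolds = sorted({a.site.scaffold for a in hits})
        lines = [
            "Sex-linkage scan results",
            "=" * 40,
            f"Sites tested:             {len(self.associations)}",
            f"Cohort:                   {len(self.model.matrix.female_indices)} F / "
            f"{len(self.model.matrix.male_indices)} M",
            f"Significance threshold:   p < {cfg.alpha:g}",
            f"HWE filter:               p >= {cfg.hwe_threshold:g} ({cfg.hwe_scope})",
            f"Significant sites:        {len(self.significant)}",
            f"Sex-specific (strict):    {len(hits)}",
            f"Scaffolds with hits:      {len(scaffolds)}",
            f"Heterogametic system:     {self.heterogametic_system()}",
        ]
        if hits:
            best = min(hits, key=lambda a: (a.fisher_p, a.site.position))
            lines.append(
                f"Top site:                 {best.site.scaffold}:{best.site.position}"
                f" (p = {best.fisher_p:.3g})"
            )
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)

    def write_manhattan_tsv(self, path: str | Path) -> None:
        self.manhattan_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------


def scan_genome(
    matrix: GenotypeMatrix, config: ScanConfig | None = None
) -> list[SiteAssociation]:
    """Whole-matrix scan; returns the per-site association list."""
    return SexLinkageModel(matrix, config).fit().associations


def rescan_region(
    matrix: GenotypeMatrix,
    scaffold: str,
    window: tuple[int, int],
    config: ScanConfig | None = None,
) -> list[SiteAssociation]:
    """Indel-inclusive re-scan of a window (matrix built with {snp, indel})."""
    return SexLinkageModel(matrix, config).fit(scaffold, window).associations
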