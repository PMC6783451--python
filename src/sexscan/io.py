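"""Genotype-matrix assembly and standard-format plumbing.

The pipeline's substrate is a sites x samples grid of diploid biallelic
genotype calls with per-sample sex labels.  Calls are encoded as small
integers (:data:`HOM_REF`, :data:`HET`, :data:`HOM_ALT`, :data:`MISSING`)
in a numpy ``int8`` array; sites and samples carry their metadata in
lightweight dataclasses.

Coordinates are 1-based inclusive throughout (VCF convention).  Any BED
export converts to 0-based half-open at the boundary and says so in its
header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# genotype call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_LABELS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class VariantClass(str, Enum):
    SNP = "snp"
    INDEL = "indel"
    OTHER = "other"


@dataclass(frozen=True)
class SexedSample:
    """A cohort member: unique id plus phenotypic sex.

    Unknown-sex samples stay in the matrix but are excluded from every
    sex-contrast computation downstream.
    """

    sample_id: str
    sex: Sex


@dataclass(frozen=True)
class VariantSite:
    """One variant locus: scaffold, 1-based position, REF and ALT alleles."""

    scaffold: str
    position: int  # 1-based bp
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.alt_alleles) != 1:
            return VariantClass.OTHER
        alt = self.alt_alleles[0]
        if len(self.ref_allele) == 1 and len(alt) == 1:
            return VariantClass.SNP
        if len(self.ref_allele) != len(alt):
            return VariantClass.INDEL
        return VariantClass.OTHER

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def net_indel_length(self) -> int:
        """len(ref) - len(alt); positive for deletions, 0 for SNPs/MNPs."""
        if not self.is_biallelic:
            return 0
        return len(self.ref_allele) - len(self.alt_alleles[0])


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype grid with sex labels.

    ``calls[i, j]`` is the call of sample ``j`` at site ``i`` using the
    module-level codes.  Within each scaffold, site positions are strictly
    increasing (validated on construction).
    """

    sites: list[VariantSite]
    samples: list[SexedSample]
    calls: np.ndarray  # (n_sites, n_samples) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        self._check_positions()

    def _check_positions(self) -> None:
        last: dict[str, int] = {}
        for s in self.sites:
            prev = last.get(s.scaffold)
            if prev is not None and s.position <= prev:
                raise ValueError(
                    f"positions not strictly increasing on {s.scaffold}: "
                    f"{prev} then {s.position}"
                )
            last[s.scaffold] = s.position

    # -- sample helpers ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sex_indices(self, sex: Sex) -> np.ndarray:
        return np.array(
            [j for j, s in enumerate(self.samples) if s.sex == sex], dtype=int
        )

    @property
    def female_indices(self) -> np.ndarray:
        return self.sex_indices(Sex.FEMALE)

    @property
    def male_indices(self) -> np.ndarray:
        return self.sex_indices(Sex.MALE)

    def sample_index(self, sample_id: str) -> int:
        for j, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return j
        raise KeyError(sample_id)

    # -- site helpers ------------------------------------------------------
    def subset_sites(self, mask: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=self.samples,
            calls=self.calls[idx],
        )

    def scaffold_site_indices(
        self, scaffold: str, window: tuple[int, int] | None = None
    ) -> np.ndarray:
        out = []
        for i, s in enumerate(self.sites):
            if s.scaffold != scaffold:
                continue
            if window is not None and not (window[0] <= s.position <= window[1]):
                continue
            out.append(i)
        return np.array(out, dtype=int)

    @property
    def scaffolds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.scaffold, None)
        return list(seen)


# ---------------------------------------------------------------------------
# sex map
# ---------------------------------------------------------------------------

_SEX_TOKENS = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
}


def read_sex_map(path: str | Path) -> list[SexedSample]:
    """Read a two-column sample\\tsex TSV (header optional).

    Sex tokens: F/female, M/male, U/unknown (case-insensitive).  Duplicate
    sample ids and unrecognised tokens are hard errors naming the row.
    """
    samples: list[SexedSample] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            sid, token = fields[0], fields[1]
            if lineno == 1 and sid.lower() in {"sample", "sample_id", "id"}:
                continue  # header
            sex = _SEX_TOKENS.get(token.lower())
            if sex is None:
                raise ValueError(
                    f"{path}:{lineno}: unrecognized sex token {token!r} for sample {sid!r}"
                )
            if sid in seen:
                raise ValueError(f"duplicate sample_id {sid}")
            seen.add(sid)
            samples.append(SexedSample(sid, sex))
    counts = {sex: sum(1 for s in samples if s.sex == sex) for sex in Sex}
    logger.info(
        "sex map %s: %d females, %d males, %d unknown (excluded from contrasts)",
        path,
        counts[Sex.FEMALE],
        counts[Sex.MALE],
        counts[Sex.UNKNOWN],
    )
    return samples


def write_sex_map(samples: Iterable[SexedSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex.value}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, samples: list[SexedSample]) -> GenotypeMatrix:
    """Parse a multi-sample VCF into a GenotypeMatrix.

    Unphased GT parsing: 0/0 -> hom_ref, 0/1 or 1/0 -> het, 1/1 -> hom_alt,
    any missing allele -> missing.  Phased separators are accepted and
    treated as unphased.  FILTER/QUAL are ignored.  For sites with a single
    ALT, a GT index >= 2 is a hard error; at multiallelic sites such calls
    are recorded as missing (the site is dropped by ``filter_biallelic``).

    Every sex-map sample must be present in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    missing = [s.sample_id for s in samples if s.sample_id not in header_samples]
    if missing:
        raise ValueError(f"sex-map samples absent from VCF {path}: {missing}")
    order = np.array([header_samples.index(s.sample_id) for s in samples])

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        alts = tuple(var.ALT)
        site = VariantSite(var.CHROM, var.POS, var.REF, alts)
        gts = np.array(var.genotypes, dtype=object)
        row = np.full(len(header_samples), MISSING, dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                row[j] = MISSING
            elif a > 1 or b > 1:
                if len(alts) == 1:
                    raise ValueError(
                        f"GT allele index >= 2 at biallelic site "
                        f"{site.scaffold}:{site.position}"
                    )
                row[j] = MISSING
            else:
                row[j] = a + b  # 0/0->0, 0/1->1, 1/1->2
        sites.append(site)
        rows.append(row[order])
    vcf.close()
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    logger.info("read %d sites x %d samples from %s", len(sites), len(samples), path)
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal VCF v4.2 (GT only) for the matrix.

    Round-trips losslessly through :func:`read_vcf` for biallelic grids.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexscan\n")
        contigs = matrix.scaffolds
        if contig_lengths:
            for name in contig_lengths:
                if name not in contigs:
                    contigs.append(name)
        for name in contigs:
            if contig_lengths and name in contig_lengths:
                fh.write(f"##contig=<ID={name},length={contig_lengths[name]}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        ids = "\t".join(s.sample_id for s in matrix.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        for i, site in enumerate(matrix.sites):
            alt = ",".join(site.alt_alleles) if site.alt_alleles else "."
            gts = "\t".join(_GT_LABELS[int(c)] for c in matrix.calls[i])
            fh.write(
                f"{site.scaffold}\t{site.position}\t.\t{site.ref_allele}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_biallelic(
    matrix: GenotypeMatrix,
    keep_classes: Iterable[VariantClass | str] = (VariantClass.SNP,),
) -> GenotypeMatrix:
    """Drop multiallelic sites and sites outside ``keep_classes``.

    The primary scan uses ``{snp}``; the region re-scan uses
    ``{snp, indel}``.  Multiallelic sites are dropped, never split.
    Idempotent.
    """
    classes = {VariantClass(c) for c in keep_classes}
    keep = np.zeros(matrix.n_sites, dtype=bool)
    n_multi = 0
    n_class = 0
    for i, site in enumerate(matrix.sites):
        if not site.is_biallelic:
            n_multi += 1
            continue
        if site.variant_class not in classes:
            n_class += 1
            continue
        keep[i] = True
    logger.info(
        "filter_biallelic: kept %d / %d sites (%d multiallelic, %d wrong class)",
        int(keep.sum()),
        matrix.n_sites,
        n_multi,
        n_class,
    )
    return matrix.subset_sites(keep)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")
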