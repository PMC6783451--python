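"""Synthetic re-sequencing cohorts with a planted sex-determination region.

The generator emulates the statistical structure the scan assumes: a
male/female diploid cohort genotyped at background SNPs in Hardy-Weinberg
equilibrium plus one recombination-suppressed core where (in an XY system)
every male is heterozygous and every female homozygous reference, with
leaky flank sites shouldering the core.  Genotyping error and missingness
are applied per call.  A TruthSet records the planted structure for
parameter-recovery tests.

All randomness derives from a single seed through named substreams
(positions/alleles, genotypes, errors, missingness, reference), so the
same seed yields byte-identical VCF/FASTA/truth outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    Sex,
    SexedSample,
    VariantSite,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SDRegionConfig:
    """Planted sex-determination region."""

    scaffold: str = "scaffold_003"
    start: int = 1_000_000
    n_core_sites: int = 30
    mean_spacing_bp: int = 200
    n_flank_sites: int = 10
    flank_leak_prob: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Cohort shape and noise model.

    Defaults mirror the study conditions being emulated: 15 males and 16
    females over several scaffolds, ~10^4 background SNPs in HWE with
    alt-allele frequency from a truncated Beta(1, 3), a ~6 kb planted core
    of 30 strictly segregating sites, 2% missing calls, no genotyping
    error.  ``core_indel_length`` > 0 turns one middle core site into a
    deletion of that net length for size-dimorphism assay fixtures.
    """

    n_males: int = 15
    n_females: int = 16
    scaffolds: tuple[tuple[str, int], ...] = (
        ("scaffold_001", 2_000_000),
        ("scaffold_002", 2_000_000),
        ("scaffold_003", 2_000_000),
        ("scaffold_004", 2_000_000),
        ("scaffold_005", 2_000_000),
    )
    n_background_sites: int = 10_000
    background_maf_beta: tuple[float, float] = (1.0, 3.0)
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    sd_region: SDRegionConfig = field(default_factory=SDRegionConfig)
    missing_rate: float = 0.02
    error_rate: float = 0.0
    system: str = "XY"  # XY | ZW
    core_indel_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.missing_rate, self.error_rate, self.sd_region.flank_leak_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.sd_region.n_core_sites < 1:
            raise ValueError("n_core_sites must be >= 1")
        if self.system not in {"XY", "ZW"}:
            raise ValueError("system must be XY or ZW")
        lengths = dict(self.scaffolds)
        if self.sd_region.scaffold not in lengths:
            raise ValueError(f"region scaffold {self.sd_region.scaffold} not in scaffolds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sd_region" in raw and isinstance(raw["sd_region"], dict):
            raw["sd_region"] = SDRegionConfig(**raw["sd_region"])
        if "scaffolds" in raw:
            raw["scaffolds"] = tuple((str(n), int(l)) for n, l in raw["scaffolds"])
        for key in ("background_maf_beta", "maf_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scaffolds"] = [list(s) for s in self.scaffolds]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


SITE_BACKGROUND = "background"
SITE_CORE = "core"
SITE_FLANK = "flank"


@dataclass
class TruthSet:
    """Planted structure: region bounds, per-site class, true sexes."""

    region_scaffold: str
    region_first_pos: int
    region_last_pos: int
    system: str
    site_classes: list[str]  # aligned with the matrix site order
    sample_sex: dict[str, str]

    def to_json_dict(self) -> dict:
        return {
            "region": {
                "scaffold": self.region_scaffold,
                "first_pos": self.region_first_pos,
                "last_pos": self.region_last_pos,
            },
            "system": self.system,
            "site_classes": self.site_classes,
            "sample_sex": self.sample_sex,
            "site_positions": (
                [[s, p] for s, p in self.site_positions]
                if self.site_positions is not None
                else None
            ),
        }

    site_positions: list[tuple[str, int]] | None = None  # aligned with site_classes

    def class_of(self, scaffold: str, position: int) -> str:
        """Planted class of a site by coordinates (background if unknown)."""
        if self.site_positions is None:
            raise ValueError("truth set carries no site coordinates")
        if not hasattr(self, "_class_map"):
            self._class_map = dict(zip(self.site_positions, self.site_classes))
        return self._class_map.get((scaffold, position), SITE_BACKGROUND)

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthSet":
        return cls(
            region_scaffold=d["region"]["scaffold"],
            region_first_pos=d["region"]["first_pos"],
            region_last_pos=d["region"]["last_pos"],
            system=d["system"],
            site_classes=list(d["site_classes"]),
            sample_sex=dict(d["sample_sex"]),
            site_positions=(
                [(s, int(p)) for s, p in d["site_positions"]]
                if d.get("site_positions") is not None
                else None
            ),
        )


def write_truth(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> TruthSet:
    with open(path) as fh:
        return TruthSet.from_json_dict(json.load(fh))


@dataclass
class SimulatedCohort:
    matrix: GenotypeMatrix
    reference: dict[str, str]
    truth: TruthSet

    def __iter__(self):
        return iter((self.matrix, self.reference, self.truth))


# ---------------------------------------------------------------------------


def _sample_positions(rng, length: int, n: int, exclude: set[int]) -> np.ndarray:
    """n distinct 1-based positions on [1, length], avoiding `exclude`."""
    out: set[int] = set()
    while len(out) < n:
        draw = rng.integers(1, length + 1, size=2 * (n - len(out)) + 8)
        for p in draw:
            p = int(p)
            if p not in exclude and p not in out:
                out.add(p)
                if len(out) == n:
                    break
    return np.sort(np.fromiter(out, dtype=int))


def _hw_genotypes(rng, q_alt: np.ndarray, n_samples: int) -> np.ndarray:
    """(n_sites, n_samples) Hardy-Weinberg draws for alt freq q per site."""
    q = q_alt[:, None]
    u = rng.random((len(q_alt), n_samples))
    p_hom_ref = (1 - q) ** 2
    p_het = 2 * q * (1 - q)
    g = np.full(u.shape, HOM_ALT, dtype=np.int8)
    g[u < p_hom_ref + p_het] = HET
    g[u < p_hom_ref] = HOM_REF
    return g


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate (matrix, reference, truth) for one seeded cohort."""
    region = config.sd_region
    lengths = dict(config.scaffolds)
    ss = np.random.SeedSequence(config.seed)
    rng_sites, rng_geno, rng_err, rng_miss, rng_ref = (
        np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(5)
    )

    # --- reference sequences -------------------------------------------
    reference = {
        name: np.frombuffer(
            _BASES[rng_ref.integers(0, 4, size=length)].tobytes(), dtype=np.uint8
        )
        .tobytes()
        .decode()
        for name, length in config.scaffolds
    }

    # --- planted positions ---------------------------------------------
    spacing = 1 + rng_sites.poisson(
        max(region.mean_spacing_bp - 1, 0), size=region.n_core_sites - 1
    )
    core_pos = region.start + np.concatenate([[0], np.cumsum(spacing)]).astype(int)
    n_left = region.n_flank_sites // 2
    n_right = region.n_flank_sites - n_left
    left_sp = 1 + rng_sites.poisson(max(region.mean_spacing_bp - 1, 0), size=n_left)
    right_sp = 1 + rng_sites.poisson(max(region.mean_spacing_bp - 1, 0), size=n_right)
    flank_pos = np.concatenate(
        [
            region.start - np.cumsum(left_sp)[::-1] if n_left else np.array([], int),
            core_pos[-1] + np.cumsum(right_sp) if n_right else np.array([], int),
        ]
    ).astype(int)
    region_len = lengths[region.scaffold]
    all_planted = np.concatenate([core_pos, flank_pos])
    if all_planted.min() < 1 or all_planted.max() > region_len:
        raise ValueError("planted region overflows its scaffold")

    # --- background positions (proportional to scaffold length) --------
    total_len = sum(lengths.values())
    planted_exclusion = {
        (region.scaffold, int(p)) for p in all_planted
    } | {
        # keep the indel's ref span clear of other variants
        (region.scaffold, int(core_pos[len(core_pos) // 2]) + k)
        for k in range(config.core_indel_length + 1)
    }
    bg: dict[str, np.ndarray] = {}
    remaining = config.n_background_sites
    names = [n for n, _ in config.scaffolds]
    for i, (name, length) in enumerate(config.scaffolds):
        n_here = (
            remaining
            if i == len(names) - 1
            else int(round(config.n_background_sites * length / total_len))
        )
        n_here = min(n_here, remaining)
        exclude = {p for s, p in planted_exclusion if s == name}
        bg[name] = _sample_positions(rng_sites, length, n_here, exclude)
        remaining -= n_here

    # --- assemble site list in scaffold order --------------------------
    sites: list[VariantSite] = []
    site_classes: list[str] = []
    site_kind: list[str] = []  # background / core / flank per matrix row
    core_sorted = np.sort(core_pos)
    indel_pos = (
        int(core_sorted[len(core_sorted) // 2]) if config.core_indel_length > 0 else None
    )
    for name, _length in config.scaffolds:
        positions = list(bg[name])
        kinds = [SITE_BACKGROUND] * len(positions)
        if name == region.scaffold:
            positions += [int(p) for p in core_sorted] + [int(p) for p in flank_pos]
            kinds += [SITE_CORE] * len(core_sorted) + [SITE_FLANK] * len(flank_pos)
        order = np.argsort(positions, kind="stable")
        ref_seq = reference[name]
        for k in order:
            pos = int(positions[k])
            ref_base = ref_seq[pos - 1]
            if kinds[k] == SITE_CORE and indel_pos is not None and pos == indel_pos:
                ref_allele = ref_seq[pos - 1 : pos + config.core_indel_length]
                alt = (ref_base,)
            else:
                ref_allele = ref_base
                others = [b for b in "ACGT" if b != ref_base]
                alt = (others[int(rng_sites.integers(0, 3))],)
            sites.append(VariantSite(name, pos, ref_allele, alt))
            site_classes.append(kinds[k])

    n_sites = len(sites)
    n_samples = config.n_males + config.n_females
    samples = [
        SexedSample(f"F{i + 1:03d}", Sex.FEMALE) for i in range(config.n_females)
    ] + [SexedSample(f"M{i + 1:03d}", Sex.MALE) for i in range(config.n_males)]
    female_cols = np.arange(config.n_females)
    male_cols = np.arange(config.n_females, n_samples)

    # --- genotypes ------------------------------------------------------
    a, b = config.background_maf_beta
    lo, hi = config.maf_bounds
    q_alt = np.clip(rng_geno.beta(a, b, size=n_sites), lo, hi)
    calls = _hw_genotypes(rng_geno, q_alt, n_samples)

    het_cols, hom_cols = (
        (male_cols, female_cols) if config.system == "XY" else (female_cols, male_cols)
    )
    classes = np.array(site_classes)
    core_rows = np.nonzero(classes == SITE_CORE)[0]
    calls[np.ix_(core_rows, het_cols)] = HET
    calls[np.ix_(core_rows, hom_cols)] = HOM_REF
    flank_rows = np.nonzero(classes == SITE_FLANK)[0]
    if len(flank_rows):
        keep_sd = (
            rng_geno.random((len(flank_rows), n_samples))
            < 1.0 - region.flank_leak_prob
        )
        sd_calls = np.empty((len(flank_rows), n_samples), dtype=np.int8)
        sd_calls[:, het_cols] = HET
        sd_calls[:, hom_cols] = HOM_REF
        calls[flank_rows] = np.where(keep_sd, sd_calls, calls[flank_rows])

    # --- error, then missingness ---------------------------------------
    if config.error_rate > 0:
        err = rng_err.random(calls.shape) < config.error_rate
        shift = 1 + (rng_err.random(calls.shape) < 0.5).astype(np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng_miss.random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)

    matrix = GenotypeMatrix(sites=sites, samples=samples, calls=calls)
    truth = TruthSet(
        region_scaffold=region.scaffold,
        region_first_pos=int(core_sorted[0]),
        region_last_pos=int(core_sorted[-1]),
        system=config.system,
        site_classes=site_classes,
        sample_sex={s.sample_id: s.sex.value for s in samples},
        site_positions=[(s.scaffold, s.position) for s in sites],
    )
    logger.info(
        "simulated cohort seed=%d: %d sites (%d core, %d flank), %dF/%dM",
        config.seed,
        n_sites,
        len(core_rows),
        len(flank_rows),
        config.n_females,
        config.n_males,
    )
    return SimulatedCohort(matrix, reference, truth)
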