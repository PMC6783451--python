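"""In-silico PCR sex assays on diagnostic variants.

The binding model is deliberately simple sequence matching, not
thermodynamics: a primer binds where its 3'-terminal ``anchor_len`` bases
match exactly and total mismatches are at most ``max_mismatches``; a
product is reported for every convergent plus/minus binding pair within
``max_product_bp``, with length measured between the outermost primer 5'
ends, inclusive (the standard amplicon-length convention).  All thresholds
are exposed in :class:`PCRParams`.

Two assay rules are modelled:

* presence — male iff the sex-specific product amplifies AND an internal
  control product amplifies; no control product means the reaction is
  uninterpretable (undetermined), mirroring the role of a mitochondrial
  internal control.
* size dimorphism — the amplicon spans an indel, so a heterozygote shows
  two product lengths (double band) and a homozygote one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Sex, VariantSite
from .report import MarkerRegion
from .scan import SiteAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PCRParams:
    anchor_len: int = 3  # 3'-terminal bases that must match exactly
    max_mismatches: int = 2  # total mismatches tolerated over the primer
    max_product_bp: int = 2000


@dataclass(frozen=True)
class PrimerPair:
    """A named primer set: one forward, one or more reverses (allele-specific
    designs carry two reverses combined at equal concentrations)."""

    name: str
    forward: str
    reverse_set: tuple[str, ...]
    expected_products: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.reverse_set:
            raise ValueError("reverse_set must be non-empty")
        for seq in (self.forward, *self.reverse_set):
            if not set(seq.upper()) <= set("ACGT"):
                raise ValueError(f"primer {seq!r} not over ACGT")


class AssayKind(str, Enum):
    PRESENCE = "presence"
    SIZE_DIMORPHISM = "size_dimorphism"


@dataclass(frozen=True)
class AssayRule:
    kind: AssayKind
    control_product_bp: int | None = None
    target_products_bp: tuple[int, ...] | None = None  # optional whitelist

    def __post_init__(self) -> None:
        if self.kind == AssayKind.PRESENCE and self.control_product_bp is None:
            raise ValueError("presence-type rule requires control_product_bp")


@dataclass(frozen=True)
class AssayProduct:
    length_bp: int
    haplotype_index: int  # 0 or 1
    primer_pair: str


class CallValue(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNDETERMINED = "undetermined"


@dataclass
class SexCall:
    sample_id: str
    call: CallValue
    evidence: list[AssayProduct] = field(default_factory=list)


# ---------------------------------------------------------------------------
# binding and amplification
# ---------------------------------------------------------------------------


def _binding_starts(
    primer: str, template: str, params: PCRParams, anchor: str = "end"
) -> np.ndarray:
    """Start indices (0-based) of windows where the primer binds.

    ``anchor`` locates the primer's 3' terminus within the match window:
    "end" for a plus-strand primer (sequence compared as-is), "start" for
    a minus-strand primer searched as its reverse complement (its 3' end
    falls on the leftmost template base of the window).
    """
    plen = len(primer)
    tlen = len(template)
    if tlen < plen:
        return np.array([], dtype=int)
    t = np.frombuffer(template.upper().encode(), dtype=np.uint8)
    p = np.frombuffer(primer.upper().encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, plen)
    mism = (windows != p).sum(axis=1)
    k = params.anchor_len
    if anchor == "end":
        anchor_mism = (windows[:, plen - k :] != p[plen - k :]).sum(axis=1)
    else:
        anchor_mism = (windows[:, :k] != p[:k]).sum(axis=1)
    return np.nonzero((mism <= params.max_mismatches) & (anchor_mism == 0))[0]


def insilico_pcr(
    pair: PrimerPair,
    haplotypes: Sequence[str],
    params: PCRParams | None = None,
) -> list[AssayProduct]:
    """Amplify each haplotype template with the primer mix.

    Every primer in the mix (forward + reverse set) is tried on both
    strands; a product arises from any plus-strand binding upstream of a
    minus-strand binding within ``max_product_bp``.  Duplicate lengths are
    deduplicated per haplotype.  A template shorter than a primer simply
    yields no products.
    """
    params = params or PCRParams()
    mix = [pair.forward, *pair.reverse_set]
    products: list[AssayProduct] = []
    for hap_idx, template in enumerate(haplotypes):
        plus: list[tuple[int, int]] = []  # (5' position = start, primer len)
        minus: list[tuple[int, int]] = []  # (3'..5' span end = start+len-1)
        for primer in mix:
            for s in _binding_starts(primer, template, params, anchor="end"):
                plus.append((int(s), len(primer)))
            rc = reverse_complement(primer)
            for s in _binding_starts(rc, template, params, anchor="start"):
                minus.append((int(s), len(primer)))
        lengths: set[int] = set()
        for p_start, p_len in plus:
            for m_start, m_len in minus:
                m_end = m_start + m_len - 1  # minus-strand primer 5' end
                if m_end <= p_start:
                    continue  # not convergent
                length = m_end - p_start + 1
                if length < p_len + m_len:
                    continue  # overlapping primers cannot form a product
                if length > params.max_product_bp:
                    continue
                lengths.add(length)
        for length in sorted(lengths):
            products.append(AssayProduct(length, hap_idx, pair.name))
    return products


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def haplotype_templates(
    reference: str,
    sites: Sequence[VariantSite],
    genotypes: Sequence[int],
    window: tuple[int, int],
) -> tuple[str, str]:
    """Build the two haplotype templates of one sample over a window.

    Heterozygous sites put the reference allele on haplotype 0 and the
    alternate on haplotype 1 (for a single sex-linked region this matches
    the gametologue structure: the variant-bearing haplotype is the
    sex-limited one).  Missing calls are treated as reference.
    ``window`` is 1-based inclusive on the reference coordinate.
    """
    start, end = window
    base = reference[start - 1 : end]
    edits: list[tuple[int, str, str, int]] = []  # (offset, ref, alt, gt)
    for site, gt in zip(sites, genotypes):
        if not (start <= site.position <= end) or not site.is_biallelic:
            continue
        if gt in (MISSING, HOM_REF):
            continue
        offset = site.position - start
        edits.append((offset, site.ref_allele, site.alt_alleles[0], int(gt)))
    haps = []
    for hap_idx in (0, 1):
        seq = base
        for offset, ref, alt, gt in sorted(edits, reverse=True):
            apply_alt = gt == HOM_ALT or (gt == HET and hap_idx == 1)
            if not apply_alt:
                continue
            if seq[offset : offset + len(ref)].upper() != ref.upper():
                raise ValueError(
                    f"reference mismatch at offset {offset}: expected {ref!r}"
                )
            seq = seq[:offset] + alt + seq[offset + len(ref) :]
        haps.append(seq)
    return haps[0], haps[1]


def design_flanking_primers(
    reference: str,
    site: VariantSite,
    name: str = "size_assay",
    primer_len: int = 20,
    flank_gap: int = 30,
) -> PrimerPair:
    """Fixture-style size-dimorphism design: primers on the reference
    flanks of an indel so the amplicon spans it.

    This is template arithmetic, not thermodynamic primer design.
    """
    pos0 = site.position - 1
    f_start = pos0 - flank_gap - primer_len
    r_start = pos0 + len(site.ref_allele) + flank_gap
    if f_start < 0 or r_start + primer_len > len(reference):
        raise ValueError("not enough reference sequence around the site")
    forward = reference[f_start : f_start + primer_len]
    reverse = reverse_complement(reference[r_start : r_start + primer_len])
    ref_product = r_start + primer_len - f_start
    alt_product = ref_product - site.net_indel_length
    return PrimerPair(
        name=name,
        forward=forward.upper(),
        reverse_set=(reverse.upper(),),
        expected_products=tuple(sorted({ref_product, alt_product})),
    )


def design_allele_specific_pair(
    reference: str,
    site: VariantSite,
    name: str = "as_assay",
    primer_len: int = 20,
    product_len: int = 150,
) -> PrimerPair:
    """Allele-specific presence design: the reverse primer's 3' base sits on
    the SNP and matches the alternate allele, so only alt-bearing
    haplotypes amplify.

    The reverse primer covers template positions [snp, snp + primer_len - 1]
    on the minus strand, so its 3' terminus pairs with the SNP base itself.
    """
    pos0 = site.position - 1
    f_start = pos0 + primer_len - product_len
    if f_start < 0 or pos0 + primer_len > len(reference):
        raise ValueError("not enough reference sequence around the site")
    forward = reference[f_start : f_start + primer_len]
    window = reference[pos0 : pos0 + primer_len]
    alt_window = site.alt_alleles[0] + window[1:]
    reverse = reverse_complement(alt_window)
    return PrimerPair(
        name=name,
        forward=forward.upper(),
        reverse_set=(reverse.upper(),),
        expected_products=(product_len,),
    )


# ---------------------------------------------------------------------------
# diagnostics, calling, accuracy
# ---------------------------------------------------------------------------


def pick_diagnostic_sites(
    region: MarkerRegion, assocs: Sequence[SiteAssociation]
) -> list[VariantSite]:
    """Sex-specific sites inside the marker block, indels first (they admit
    size-dimorphism designs), then SNPs by (p, position)."""
    blk = region.block
    hits = [
        a
        for a in assocs
        if a.sex_specific
        and a.site.scaffold == region.scaffold
        and blk.first_pos <= a.site.position <= blk.last_pos
    ]
    indels = [a for a in hits if a.site.variant_class.value == "indel"]
    snps = [a for a in hits if a.site.variant_class.value == "snp"]
    indels.sort(key=lambda a: (a.fisher_p, a.site.position))
    snps.sort(key=lambda a: (a.fisher_p, a.site.position))
    return [a.site for a in indels + snps]


def call_sex(
    products: Sequence[AssayProduct],
    rule: AssayRule,
    sample_id: str = "",
) -> SexCall:
    """Interpret a product list under an assay rule.

    presence: male iff target and control products both present; female iff
    control present without target; undetermined iff control absent.
    size dimorphism: male iff >= 2 distinct target lengths, female iff
    exactly 1, undetermined iff 0.
    """
    lengths = [p.length_bp for p in products]
    control = rule.control_product_bp
    if rule.kind == AssayKind.PRESENCE:
        control_present = control in lengths
        if rule.target_products_bp is not None:
            target_present = any(l in rule.target_products_bp for l in lengths)
        else:
            target_present = any(l != control for l in lengths)
        if not control_present:
            value = CallValue.UNDETERMINED
        elif target_present:
            value = CallValue.MALE
        else:
            value = CallValue.FEMALE
    else:
        target_lengths = {l for l in lengths if control is None or l != control}
        if rule.target_products_bp is not None:
            target_lengths &= set(rule.target_products_bp)
        if len(target_lengths) >= 2:
            value = CallValue.MALE
        elif len(target_lengths) == 1:
            value = CallValue.FEMALE
        else:
            value = CallValue.UNDETERMINED
    return SexCall(sample_id, value, list(products))


@dataclass
class AccuracyReport:
    accuracy: float
    n_total: int
    n_correct: int
    per_sex: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "per_sex": self.per_sex,
        }


def assay_accuracy(
    calls: Sequence[SexCall], truth: Mapping[str, Sex | str]
) -> AccuracyReport:
    """Fraction of calls matching known sex; undetermined counts as wrong."""
    n_correct = 0
    by_sex: dict[str, list[bool]] = {}
    for c in calls:
        if c.sample_id not in truth:
            raise KeyError(f"sample {c.sample_id} not in truth map")
        true_sex = Sex(truth[c.sample_id]).value
        ok = c.call.value == true_sex
        n_correct += ok
        by_sex.setdefault(true_sex, []).append(ok)
    n = len(calls)
    per_sex = {sex: sum(v) / len(v) for sex, v in by_sex.items()}
    return AccuracyReport(n_correct / n if n else 0.0, n, n_correct, per_sex)


def run_assay(
    matrix: GenotypeMatrix,
    reference: Mapping[str, str],
    pair: PrimerPair,
    rule: AssayRule,
    target_scaffold: str,
    window: tuple[int, int],
    control_products: Sequence[AssayProduct] = (),
    params: PCRParams | None = None,
) -> list[SexCall]:
    """Evaluate the assay on every cohort sample.

    Templates are built per sample from the reference plus its genotypes
    in ``window``; ``control_products`` (e.g. from a mitochondrial
    control reaction that amplifies in everyone) are appended to each
    sample's product list before calling.
    """
    ref_seq = reference[target_scaffold]
    idx = matrix.scaffold_site_indices(target_scaffold, window)
    sites = [matrix.sites[i] for i in idx]
    calls: list[SexCall] = []
    for j, sample in enumerate(matrix.samples):
        genotypes = [int(matrix.calls[i, j]) for i in idx]
        haps = haplotype_templates(ref_seq, sites, genotypes, window)
        products = insilico_pcr(pair, haps, params) + list(control_products)
        calls.append(call_sex(products, rule, sample.sample_id))
    return calls
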