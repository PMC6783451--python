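"""Per-scaffold aggregation of scan results and marker-region selection.

A scaffold summary counts total and sex-specific sites, bounds the
sex-specific region (min/max hit positions, inclusive size), and attaches
the scaffold's LD blocks.  The marker region — where diagnostic PCR
targets are taken from — is the largest LD block among scaffolds carrying
more than ``min_sites`` sex-specific variants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import GenotypeMatrix, VariantSite
from .ld import LDBlock, block_span
from .scan import SiteAssociation

logger = logging.getLogger(__name__)


@dataclass
class ScaffoldSummary:
    scaffold: str
    scaffold_size_bp: int
    n_total_sites: int
    n_sex_specific: int
    region_start: int
    region_end: int
    n_ld_blocks: int = 0
    max_block: LDBlock | None = None
    sex_specific_sites: list[SiteAssociation] = field(default_factory=list)

    @property
    def region_size_bp(self) -> int:
        return block_span(self.region_start, self.region_end)


@dataclass
class MarkerRegion:
    scaffold: str
    block: LDBlock
    member_sex_specific_sites: list[VariantSite]

    def to_json(self) -> str:
        return json.dumps(
            {
                "scaffold": self.scaffold,
                "block": {
                    "first_pos": self.block.first_pos,
                    "last_pos": self.block.last_pos,
                    "span_bp": self.block.span_bp,
                    "n_markers": self.block.n_markers,
                },
                "member_sex_specific_sites": [
                    {
                        "scaffold": s.scaffold,
                        "position": s.position,
                        "ref": s.ref_allele,
                        "alt": list(s.alt_alleles),
                    }
                    for s in self.member_sex_specific_sites
                ],
            },
            indent=2,
        )


def _max_block(blocks: Sequence[LDBlock]) -> LDBlock | None:
    if not blocks:
        return None
    return max(blocks, key=lambda b: (b.span_bp, b.n_markers, -b.first_pos))


def summarize_scaffolds(
    assocs: Sequence[SiteAssociation],
    blocks: Mapping[str, Sequence[LDBlock]] | None = None,
    matrix: GenotypeMatrix | None = None,
    scaffold_sizes: Mapping[str, int] | None = None,
) -> list[ScaffoldSummary]:
    """One summary per scaffold containing at least one sex-specific site.

    ``n_total_sites`` counts post-filter sites per scaffold from the
    matrix; region bounds are the min/max sex-specific positions.
    """
    blocks = blocks or {}
    hits_by_scaffold: dict[str, list[SiteAssociation]] = {}
    for a in assocs:
        if a.sex_specific:
            hits_by_scaffold.setdefault(a.site.scaffold, []).append(a)

    totals: dict[str, int] = {}
    if matrix is not None:
        for s in matrix.sites:
            totals[s.scaffold] = totals.get(s.scaffold, 0) + 1
    else:
        for a in assocs:
            totals[a.site.scaffold] = totals.get(a.site.scaffold, 0) + 1

    summaries = []
    for scaffold, hits in hits_by_scaffold.items():
        positions = [a.site.position for a in hits]
        scaffold_blocks = list(blocks.get(scaffold, []))
        size = (scaffold_sizes or {}).get(scaffold, max(positions))
        summaries.append(
            ScaffoldSummary(
                scaffold=scaffold,
                scaffold_size_bp=size,
                n_total_sites=totals.get(scaffold, len(hits)),
                n_sex_specific=len(hits),
                region_start=min(positions),
                region_end=max(positions),
                n_ld_blocks=len(scaffold_blocks),
                max_block=_max_block(scaffold_blocks),
                sex_specific_sites=sorted(hits, key=lambda a: a.site.position),
            )
        )
    summaries.sort(key=lambda s: s.scaffold)
    return summaries


def select_marker_region(
    summaries: Sequence[ScaffoldSummary],
    min_sites: int = 10,
    metric: str = "block_span",  # block_span | n_sites
) -> MarkerRegion | None:
    """Pick the marker region: the largest LD block among scaffolds with
    strictly more than ``min_sites`` sex-specific sites.

    Ties break by more member sex-specific sites, then scaffold name.
    Returns None when no scaffold is eligible.
    """
    eligible = [
        s for s in summaries if s.n_sex_specific > min_sites and s.max_block is not None
    ]
    if not eligible:
        logger.info("select_marker_region: no eligible scaffold")
        return None

    def members(s: ScaffoldSummary) -> list[VariantSite]:
        blk = s.max_block
        return [
            a.site
            for a in s.sex_specific_sites
            if blk.first_pos <= a.site.position <= blk.last_pos
        ]

    if metric == "n_sites":
        key = lambda s: (s.n_sex_specific, s.max_block.span_bp)
    else:
        key = lambda s: (s.max_block.span_bp, len(members(s)))
    # max() keeps the first maximal element, so sorting by name first makes
    # the lexicographically smallest scaffold win remaining ties
    best = max(sorted(eligible, key=lambda s: s.scaffold), key=key)
    return MarkerRegion(best.scaffold, best.max_block, members(best))


def report_frame(summaries: Sequence[ScaffoldSummary]) -> pd.DataFrame:
    """Report table: one row per scaffold with region and block columns."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "scaffold": s.scaffold,
                "scaffold_size_bp": s.scaffold_size_bp,
                "n_total_snps": s.n_total_sites,
                "n_sex_specific": s.n_sex_specific,
                "region_start_bp": s.region_start,
                "region_end_bp": s.region_end,
                "region_size_bp": s.region_size_bp,
                "n_ld_blocks": s.n_ld_blocks,
                "max_block_size_bp": s.max_block.span_bp if s.max_block else 0,
                "max_block_start_bp": s.max_block.first_pos if s.max_block else 0,
                "max_block_end_bp": s.max_block.last_pos if s.max_block else 0,
            }
        )
    return pd.DataFrame(rows)
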