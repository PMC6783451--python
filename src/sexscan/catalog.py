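"""Published male-marker catalogue for Pacific bluefin tuna (Thunnus orientalis).

The package ships the published survey results for the wild cohort of 31
individuals (16 females, 15 males) re-sequenced against the 444-scaffold
draft assembly: the 51 male-specific variants of the scaffold_064
sex-determining region with their per-sex genotype counts, and the
per-scaffold summary of all 16 scaffolds carrying sex-specific SNPs
(with LD-block bounds for the seven scaffolds that carried more than ten).
These printed values serve as worked-example inputs: re-running the exact
test and the strict-segregation classifier on the catalogued genotype
configurations must reproduce the published p-values and flags.

The region's one indel is catalogued as a deletion GTAATGTAG -> G
(net 8 bp) at 3,724,697 bp.
"""

from __future__ import annotations

import pandas as pd

# 51 variants of the scaffold_064 male-determining region.
# (position, ref, alt, n_het_males); females are 16/0/0 (hom ref) at every
# site, males 0/k/0 with k = 15 except one site genotyped in 14 males.
_MARKER_ROWS = [
    (3723782, "A", "T", 15),
    (3723876, "A", "G", 15),
    (3723925, "T", "C", 15),
    (3724050, "C", "T", 15),
    (3724051, "A", "G", 15),
    (3724070, "A", "G", 15),
    (3724479, "G", "T", 15),
    (3724481, "T", "G", 15),
    (3724494, "C", "T", 15),
    (3724556, "C", "T", 15),
    (3724561, "C", "A", 15),
    (3724625, "T", "G", 15),
    (3724697, "GTAATGTAG", "G", 15),
    (3725864, "T", "C", 15),
    (3725869, "G", "A", 15),
    (3725870, "C", "T", 15),
    (3725892, "C", "T", 15),
    (3725903, "G", "A", 15),
    (3725915, "G", "A", 15),
    (3725924, "G", "C", 15),
    (3725968, "G", "A", 15),
    (3725974, "G", "A", 15),
    (3726082, "A", "G", 15),
    (3726098, "C", "T", 15),
    (3726136, "G", "T", 15),
    (3726155, "A", "G", 15),
    (3726182, "G", "T", 15),
    (3726338, "G", "C", 15),
    (3726374, "T", "C", 15),
    (3726420, "G", "A", 15),
    (3726427, "A", "T", 15),
    (3726477, "C", "T", 15),
    (3726480, "T", "A", 15),
    (3726530, "C", "T", 15),
    (3726649, "G", "T", 15),
    (3726723, "T", "A", 14),
    (3726751, "A", "G", 15),
    (3726760, "C", "T", 15),
    (3726826, "C", "T", 15),
    (3727016, "C", "T", 15),
    (3727037, "A", "G", 15),
    (3727050, "C", "T", 15),
    (3727069, "C", "T", 15),
    (3729537, "C", "A", 15),
    (3729736, "C", "T", 15),
    (3729866, "T", "C", 15),
    (3730062, "C", "A", 15),
    (3730221, "C", "T", 15),
    (3730222, "G", "A", 15),
    (3730268, "C", "T", 15),
    (3730295, "T", "A", 15),
]

MARKER_SCAFFOLD = "scaffold_064"
N_FEMALES = 16
N_MALES = 15

# Per-scaffold published summary; LD fields are None for scaffolds with
# <= 10 sex-specific SNPs (no block analysis was published for them).
# columns: scaffold, scaffold_size_bp, n_total_snps, n_sex_specific,
#          region_start, region_end, region_size,
#          n_ld_blocks, max_block_bp, ld_start, ld_end
_SCAFFOLD_ROWS = [
    ("scaffold_002", 19_343_486, 634_171, 2, 1_411_525, 1_411_537, 13, None, None, None, None),
    ("scaffold_004", 15_333_484, 729_773, 58, 13_755_422, 13_757_959, 2538, 21, 406, 13_757_866, 13_758_271),
    ("scaffold_008", 13_582_522, 414_429, 18, 13_181_867, 13_182_926, 1060, 6, 71, 13_182_469, 13_182_539),
    ("scaffold_012", 11_623_986, 535_318, 4, 6_658_078, 6_658_121, 44, None, None, None, None),
    ("scaffold_016", 10_992_500, 349_783, 4, 5_851_008, 5_851_271, 264, None, None, None, None),
    ("scaffold_024", 9_474_074, 378_040, 2, 4_640_584, 4_641_391, 808, None, None, None, None),
    ("scaffold_040", 6_874_678, 235_900, 1, 6_336_490, 6_336_490, 1, None, None, None, None),
    ("scaffold_047", 5_831_790, 228_235, 32, 2_802_518, 2_810_509, 7992, 23, 208, 2_810_382, 2_810_589),
    ("scaffold_061", 4_681_469, 154_850, 29, 1_942_591, 2_033_284, 90694, 206, 307, 2_026_362, 2_026_668),
    ("scaffold_064", 4_535_926, 89_006, 44, 3_723_782, 3_730_295, 6514, 4, 3174, 3_723_703, 3_726_876),
    ("scaffold_081", 3_464_053, 53_509, 2, 3_407_626, 3_407_890, 265, None, None, None, None),
    ("scaffold_082", 3_452_009, 163_342, 11, 620_729, 620_873, 145, 1, 185, 620_689, 620_873),
    ("scaffold_150", 749_403, 5_889, 41, 54_606, 58_731, 4126, 19, 1204, 56_072, 57_275),
    ("scaffold_187", 294_664, 3_161, 1, 6, 1_626, 1621, None, None, None, None),
    ("scaffold_208", 153_918, 1_173, 1, 139_056, 139_056, 1, None, None, None, None),
]


def marker_catalog() -> pd.DataFrame:
    """The 51-variant male-marker catalogue with per-sex genotype counts."""
    rows = []
    for pos, ref, alt, k in _MARKER_ROWS:
        rows.append(
            {
                "scaffold": MARKER_SCAFFOLD,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "female_counts": (N_FEMALES, 0, 0),
                "male_counts": (0, k, 0),
            }
        )
    return pd.DataFrame(rows)


def scaffold_catalog() -> pd.DataFrame:
    """Published per-scaffold summary of sex-specific SNPs and LD blocks."""
    cols = [
        "scaffold",
        "scaffold_size_bp",
        "n_total_snps",
        "n_sex_specific",
        "region_start",
        "region_end",
        "region_size_bp",
        "n_ld_blocks",
        "max_block_bp",
        "ld_start",
        "ld_end",
    ]
    return pd.DataFrame(_SCAFFOLD_ROWS, columns=cols)
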