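"""End-to-end orchestration: simulate/load -> scan -> LD blocks -> report ->
assay, with deterministic outputs and per-stage accounting.

``run_discovery`` is the in-memory core shared by the CLI and the test
suite; ``run_pipeline`` adds file I/O around it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .assay import (
    AssayKind,
    AssayRule,
    PCRParams,
    assay_accuracy,
    design_flanking_primers,
    pick_diagnostic_sites,
    run_assay,
)
from .io import (
    GenotypeMatrix,
    VariantClass,
    filter_biallelic,
    read_sex_map,
    read_vcf,
    write_fasta,
    write_sex_map,
    write_vcf,
)
from .ld import LDBlock, LDConfig, gabriel_blocks
from .report import (
    MarkerRegion,
    ScaffoldSummary,
    report_frame,
    select_marker_region,
    summarize_scaffolds,
)
from .scan import ScanConfig, ScanResults, SexLinkageModel
from .simulate import CohortConfig, SimulatedCohort, simulate_cohort, write_truth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Composed stage configuration.

    Either ``vcf``+``sex_map`` paths or a ``simulate`` stanza must be
    given.  ``ld_window_margin_bp`` bounds block-finding to the
    sex-specific region plus margin on each candidate scaffold.
    """

    vcf: str | None = None
    sex_map: str | None = None
    reference_fasta: str | None = None
    simulate: CohortConfig | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    ld: LDConfig = field(default_factory=LDConfig)
    min_sites_for_region: int = 10
    ld_window_margin_bp: int = 5000
    run_assay_stage: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("simulate") is not None:
            sim = dict(raw["simulate"])
            from .simulate import SDRegionConfig

            if "sd_region" in sim and isinstance(sim["sd_region"], dict):
                sim["sd_region"] = SDRegionConfig(**sim["sd_region"])
            if "scaffolds" in sim:
                sim["scaffolds"] = tuple((str(n), int(l)) for n, l in sim["scaffolds"])
            raw["simulate"] = CohortConfig(**sim)
        if "scan" in raw and isinstance(raw["scan"], dict):
            raw["scan"] = ScanConfig(**raw["scan"])
        if "ld" in raw and isinstance(raw["ld"], dict):
            raw["ld"] = LDConfig(**raw["ld"])
        return cls(**raw)

    def to_yaml_str(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class DiscoveryResult:
    results: ScanResults
    blocks: dict[str, list[LDBlock]]
    summaries: list[ScaffoldSummary]
    marker_region: MarkerRegion | None


def run_discovery(
    matrix: GenotypeMatrix,
    scan_config: ScanConfig | None = None,
    ld_config: LDConfig | None = None,
    min_sites_for_region: int = 10,
    ld_window_margin_bp: int = 5000,
    scaffold_sizes: Mapping[str, int] | None = None,
) -> DiscoveryResult:
    """Scan the matrix, partition candidate regions into LD blocks, and
    select the marker region.

    Block-finding runs on each scaffold carrying more than
    ``min_sites_for_region`` sex-specific sites, over the sex-specific
    region widened by ``ld_window_margin_bp`` on each side (all eligible
    markers there participate, not only the significant ones).
    """
    scan_config = scan_config or ScanConfig()
    ld_config = ld_config or LDConfig()
    results = SexLinkageModel(matrix, scan_config).fit()

    hits_by_scaffold: dict[str, list[int]] = {}
    for a in results.sex_specific:
        hits_by_scaffold.setdefault(a.site.scaffold, []).append(a.site.position)
    blocks: dict[str, list[LDBlock]] = {}
    for scaffold, positions in hits_by_scaffold.items():
        if len(positions) <= min_sites_for_region:
            continue
        window = (
            max(1, min(positions) - ld_window_margin_bp),
            max(positions) + ld_window_margin_bp,
        )
        blocks[scaffold] = gabriel_blocks(matrix, scaffold, ld_config, window)

    summaries = summarize_scaffolds(
        results.associations, blocks, matrix, scaffold_sizes
    )
    region = select_marker_region(summaries, min_sites=min_sites_for_region)
    return DiscoveryResult(results, blocks, summaries, region)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all stages and write the output directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"sexscan {__version__}", f"seed {config.seed}"]
    (out / "config.yaml").write_text(config.to_yaml_str())

    reference: Mapping[str, str] | None = None
    truth = None
    scaffold_sizes: dict[str, int] | None = None
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        cohort: SimulatedCohort = simulate_cohort(sim_cfg)
        matrix, reference, truth = cohort
        scaffold_sizes = {n: l for n, l in sim_cfg.scaffolds}
        write_vcf(matrix, out / "cohort.vcf", scaffold_sizes)
        write_fasta(reference, out / "reference.fasta")
        write_sex_map(matrix.samples, out / "sex_map.tsv")
        write_truth(truth, out / "truth.json")
        log_lines.append(f"simulated {matrix.n_sites} sites x {matrix.n_samples} samples")
        n_raw = matrix.n_sites
        matrix_snp = filter_biallelic(matrix, {VariantClass.SNP})
        matrix_all = filter_biallelic(matrix, {VariantClass.SNP, VariantClass.INDEL})
    else:
        if not config.vcf or not config.sex_map:
            raise ValueError("config field 'vcf' and 'sex_map' are required without a simulate stanza")
        samples = read_sex_map(config.sex_map)
        raw = read_vcf(config.vcf, samples)
        n_raw = raw.n_sites
        matrix_snp = filter_biallelic(raw, {VariantClass.SNP})
        matrix_all = filter_biallelic(raw, {VariantClass.SNP, VariantClass.INDEL})
        if config.reference_fasta:
            from .io import read_fasta

            reference = read_fasta(config.reference_fasta)
    log_lines.append(
        f"sites: {n_raw} raw, {matrix_snp.n_sites} biallelic SNPs, "
        f"{matrix_all.n_sites} biallelic SNPs+indels "
        f"(dropped {n_raw - matrix_all.n_sites} multiallelic/other)"
    )

    # primary SNP scan + blocks + report
    disc = run_discovery(
        matrix_snp,
        config.scan,
        config.ld,
        config.min_sites_for_region,
        config.ld_window_margin_bp,
        scaffold_sizes,
    )
    disc.results.write_tsv(out / "associations.tsv")
    disc.results.write_manhattan_tsv(out / "manhattan.tsv")
    report_frame(disc.summaries).to_csv(out / "scaffold_report.tsv", sep="\t", index=False)
    log_lines.append(disc.results.summary())

    block_rows = []
    for scaffold, blks in disc.blocks.items():
        for blk in blks:
            block_rows.append(
                f"{scaffold}\t{blk.first_pos}\t{blk.last_pos}\t{blk.span_bp}\t{blk.n_markers}"
            )
    (out / "ld_blocks.tsv").write_text(
        "scaffold\tfirst_pos\tlast_pos\tspan_bp\tn_markers\n" + "".join(r + "\n" for r in block_rows)
    )

    # indel-inclusive re-scan of the marker region
    rescan_assocs = []
    if disc.marker_region is not None:
        region = disc.marker_region
        summary = next(s for s in disc.summaries if s.scaffold == region.scaffold)
        window = (summary.region_start, summary.region_end)
        rescan_assocs = (
            SexLinkageModel(matrix_all, config.scan).fit(region.scaffold, window).associations
        )
        (out / "marker_region.json").write_text(region.to_json() + "\n")
        log_lines.append(
            f"marker region: {region.scaffold} block {region.block.first_pos}-"
            f"{region.block.last_pos} ({region.block.span_bp} bp), rescan found "
            f"{sum(a.sex_specific for a in rescan_assocs)} sex-specific variants in "
            f"{window[0]}-{window[1]}"
        )

    # assay stage (needs a reference and a diagnostic indel in the region)
    if (
        config.run_assay_stage
        and disc.marker_region is not None
        and reference is not None
    ):
        region = disc.marker_region
        assoc_pool = rescan_assocs or disc.results.associations
        diagnostics = pick_diagnostic_sites(region, assoc_pool)
        indels = [s for s in diagnostics if s.variant_class == VariantClass.INDEL]
        if not indels:
            # no indel inside the block itself: fall back to sex-specific
            # indels anywhere in the candidate region
            indels = sorted(
                (
                    a.site
                    for a in assoc_pool
                    if a.sex_specific and a.site.variant_class == VariantClass.INDEL
                ),
                key=lambda s: s.position,
            )
        if indels:
            target = indels[0]
            pair = design_flanking_primers(reference[region.scaffold], target)
            rule = AssayRule(AssayKind.SIZE_DIMORPHISM)
            window = (target.position - 200, target.position + 200)
            calls = run_assay(
                matrix_all, reference, pair, rule, region.scaffold, window
            )
            truth_map = (
                truth.sample_sex
                if truth is not None
                else {s.sample_id: s.sex.value for s in matrix_all.samples}
            )
            acc = assay_accuracy(calls, truth_map)
            with open(out / "assay_calls.tsv", "w") as fh:
                fh.write("sample_id\tcall\tproducts\n")
                for c in calls:
                    prods = ",".join(str(p.length_bp) for p in c.evidence)
                    fh.write(f"{c.sample_id}\t{c.call.value}\t{prods}\n")
            (out / "accuracy.json").write_text(
                json.dumps(acc.to_json_dict(), indent=2, sort_keys=True) + "\n"
            )
            log_lines.append(
                f"assay: size-dimorphism at {target.scaffold}:{target.position}, "
                f"accuracy {acc.accuracy:.4f} over {acc.n_total} samples"
            )
        else:
            log_lines.append("assay: no diagnostic indel in marker region; stage skipped")

    (out / "run_log.txt").write_text("".join(line + "\n" for line in log_lines))
    return out
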