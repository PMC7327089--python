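"""End-to-end pipeline: calling -> cohort statistics -> association suite.

:func:`analyze_cohort` runs on in-memory tables (what the tests and the
simulator exercise); :func:`run_pipeline` is the file-driven wrapper that
reads the configured inputs, calls :func:`analyze_cohort` and writes every
output table plus a JSON report carrying a provenance block (package
version, configuration hash, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import calling, cohort, associations
from . import io as _io
from .exceptions import DependencyError
from .io import PipelineConfig

__all__ = ["PipelineResult", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    snp_calls: pd.DataFrame
    gene_calls: pd.DataFrame
    proportions: pd.DataFrame
    gene_frequencies: pd.DataFrame
    snp_frequencies: pd.DataFrame
    ratio_statistics: pd.DataFrame
    report: list
    stage_counts: dict = field(default_factory=dict)
    bias_map: pd.DataFrame | None = None
    high_frequency: dict = field(default_factory=dict)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.report:
            d = r.to_dict()
            d.update(d.pop("effect"))
            rows.append(d)
        return pd.DataFrame(rows)


def _cohort_sizes(counts: pd.DataFrame) -> dict:
    return (
        counts.groupby("tissue")["sample_id"].nunique().to_dict()
        if len(counts)
        else {}
    )


def analyze_cohort(
    counts: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    dna_counts: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run calling, cohort statistics and the association suite.

    Stage record counts (input, known-variant surviving, editing-filter
    surviving, depth-filter surviving, testable gene-samples) are kept in
    ``stage_counts``; they are non-increasing along the pipeline.
    """
    cfg = config or PipelineConfig()
    stage_counts = {"input_records": len(counts)}

    if cfg.require_known_variant:
        counts = calling.drop_unknown_variants(counts, snp_annotation)
    stage_counts["known_variant_records"] = len(counts)
    if cfg.apply_editing_filter:
        counts = associations.rna_editing_filter(counts, snp_annotation)
    stage_counts["post_editing_records"] = len(counts)

    surviving = calling.filter_counts(counts, cfg.min_allele, cfg.min_depth)
    stage_counts["depth_filter_records"] = len(surviving)
    snp_calls = calling.call_snps(surviving, cfg.p_cutoff, cfg.min_allele, cfg.min_depth)
    gene_calls = calling.call_genes(snp_calls, cfg.p_cutoff, cfg.snp_mode)
    if cfg.fdr_mode:
        gene_calls = calling.fdr_correct(gene_calls, cfg.p_cutoff)
    stage_counts["testable_gene_samples"] = len(gene_calls)

    bias_map = None
    if dna_counts is not None and len(dna_counts):
        dna = dna_counts
        if cfg.require_known_variant:
            dna = calling.drop_unknown_variants(dna, snp_annotation)
        bias_map = calling.detect_allele_bias(
            dna, cfg.p_cutoff, cfg.min_allele, cfg.min_depth
        )
        gene_calls = calling.remove_biased(
            gene_calls, bias_map, exclude=cfg.exclude_allele_biased
        )
        stage_counts["post_bias_gene_samples"] = len(gene_calls)
    elif cfg.exclude_allele_biased:
        raise DependencyError("allele-bias exclusion requested but no DNA counts given")

    sizes = _cohort_sizes(counts)
    exclude = cfg.exclude_allele_biased
    proportions = cohort.sample_aei_proportions(gene_calls, exclude_biased=exclude)
    gene_freq = cohort.unit_aei_frequency(
        gene_calls, "gene", sizes, cfg.testable_frac, exclude_biased=exclude
    )
    snp_freq = cohort.unit_aei_frequency(
        snp_calls.assign(testable=True), "snp", sizes, cfg.testable_frac,
        exclude_biased=False,
    )
    adjacent_calls = gene_calls.loc[gene_calls["tissue"] == "adjacent"]
    major_map = cohort.assign_major_minor(adjacent_calls)
    aei_genes = set(
        adjacent_calls.loc[adjacent_calls["is_aei"].astype(bool), "gene_id"]
    )
    ratio_df = cohort.ratio_stats(
        gene_calls, major_map, cfg.min_ratio_samples, genes=aei_genes,
        exclude_biased=exclude,
    )

    report = associations.run_association_suite(
        proportions=proportions,
        snp_frequencies=snp_freq,
        gene_frequencies=gene_freq,
        ratio_statistics=ratio_df,
        snp_calls=snp_calls,
        snp_annotation=snp_annotation,
        gene_annotation=gene_annotation,
        p_cutoff=cfg.p_cutoff,
        paired=cfg.paired_tests,
        label="",
    )

    # Sensitivity re-runs on stricter inputs, when they add information.
    if bias_map is not None and not cfg.exclude_allele_biased:
        calls_nb = calling.remove_biased(gene_calls, bias_map, exclude=True)
        props_nb = cohort.sample_aei_proportions(calls_nb)
        try:
            report.append(
                associations._patient_paired(
                    props_nb, "aei_proportion_tumor_vs_adjacent{no_allele_bias}",
                    cfg.paired_tests,
                )
            )
        except Exception as exc:  # degenerate after exclusion
            report.append(
                associations.TestResult(
                    "aei_proportion_tumor_vs_adjacent{no_allele_bias}",
                    status="skipped", reason=str(exc),
                )
            )
    elif dna_counts is None:
        report.append(
            associations.TestResult(
                "aei_proportion_tumor_vs_adjacent{no_allele_bias}",
                status="skipped", reason="no DNA counts supplied",
            )
        )
    if not cfg.apply_editing_filter:
        kept = associations.rna_editing_filter(snp_calls, snp_annotation)
        groups = associations.consequence_groups(kept, snp_annotation, cfg.p_cutoff)
        for tissue, sub in groups.groupby("tissue", sort=True):
            try:
                report.append(
                    associations.paired_t_test(
                        sub["prop_nonsyn"], sub["prop_syn"],
                        name=f"nonsyn_vs_syn_proportion[{tissue}]{{no_ag_editing}}",
                        paired=cfg.paired_tests,
                    )
                )
            except Exception as exc:
                report.append(
                    associations.TestResult(
                        f"nonsyn_vs_syn_proportion[{tissue}]{{no_ag_editing}}",
                        status="skipped", reason=str(exc),
                    )
                )

    hi = {}
    for unit_name, freq in (("gene", gene_freq), ("snp", snp_freq)):
        if len(freq):
            hi[unit_name] = cohort.high_frequency_units(freq, cfg.hi_freq_quantile)
    for name, count in stage_counts.items():
        logger.info("stage %s: %d records", name, count)
    return PipelineResult(
        snp_calls=snp_calls,
        gene_calls=gene_calls,
        proportions=proportions,
        gene_frequencies=gene_freq,
        snp_frequencies=snp_freq,
        ratio_statistics=ratio_df,
        report=report,
        stage_counts=stage_counts,
        bias_map=bias_map,
        high_frequency=hi,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven pipeline: read inputs, analyze, write the output set."""
    if config.counts_path is None or config.output_dir is None:
        raise DependencyError("run_pipeline requires counts_path and output_dir")
    if config.snp_annotation_path is None or config.gene_annotation_path is None:
        raise DependencyError("run_pipeline requires both annotation paths")
    counts = _io.read_counts(config.counts_path)
    snp_ann, gene_ann = _io.read_annotations(
        config.snp_annotation_path, config.gene_annotation_path
    )
    dna = None
    if config.dna_counts_path is not None:
        dna = _io.read_counts(config.dna_counts_path)
    result = analyze_cohort(counts, snp_ann, gene_ann, dna, config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_table(result.gene_calls, outdir / "gene_calls.tsv")
    _io.write_table(result.proportions, outdir / "sample_proportions.tsv")
    _io.write_table(result.gene_frequencies, outdir / "gene_frequencies.tsv")
    _io.write_table(result.snp_frequencies, outdir / "snp_frequencies.tsv")
    _io.write_table(result.ratio_statistics, outdir / "ratio_stats.tsv")
    report_frame = result.report_frame()
    _io.write_table(report_frame, outdir / "report.tsv")

    # High-frequency gene lists: tumor group, adjacent group, and the
    # background of genes reported in both tissues.
    gene_hi = result.high_frequency.get("gene")
    if gene_hi is not None:
        by_tissue = {
            t: set(sub["unit_id"]) for t, sub in gene_hi.groupby("tissue")
        }
        gf = result.gene_frequencies
        tissues_per_gene = gf.groupby("unit_id")["tissue"].nunique()
        background = sorted(tissues_per_gene[tissues_per_gene >= 2].index)
        tumor_hi = sorted(by_tissue.get("tumor", set()) - by_tissue.get("adjacent", set()))
        adj_hi = sorted(by_tissue.get("adjacent", set()) - by_tissue.get("tumor", set()))
        (outdir / "high_frequency_tumor_group.txt").write_text("\n".join(tumor_hi) + "\n")
        (outdir / "high_frequency_adjacent_group.txt").write_text("\n".join(adj_hi) + "\n")
        (outdir / "background_genes.txt").write_text("\n".join(background) + "\n")

    payload = {
        "provenance": {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "config": config.to_dict(),
        },
        "stage_counts": result.stage_counts,
        "tests": [r.to_dict() for r in result.report],
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return result
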