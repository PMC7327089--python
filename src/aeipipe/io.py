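"""Readers and writers for the pipeline's tabular and VCF interfaces.

Tables are tab-separated UTF-8 with a mandatory header row and ``.`` for
missing values; genomic coordinates are 1-based inclusive everywhere (the
VCF convention), including TSVs.

Counts table schema (``counts.tsv`` and ``dna_counts.tsv``)::

    sample_id  patient_id  tissue  chrom  pos  snp_id  gene_id  ref  alt
    ref_count  alt_count

SNP annotation: ``snp_id gene_id strand consequence conservation
known_variant``; gene annotation: ``gene_id dn ds dnds`` (dnds empty when
ds = 0).  VCF input must carry per-sample ``AD`` (allelic depth); only
``GT=0/1`` genotypes become records, others are skipped and counted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

__all__ = [
    "PipelineConfig",
    "COUNT_COLUMNS",
    "read_table",
    "write_table",
    "read_counts",
    "write_counts",
    "read_annotations",
    "write_vcf_per_patient",
    "read_counts_vcf",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "sample_id", "patient_id", "tissue", "chrom", "pos", "snp_id",
    "gene_id", "ref", "alt", "ref_count", "alt_count",
]

_TISSUES = {"tumor", "adjacent"}
_CONSEQUENCES = {"synonymous", "nonsynonymous", "other"}


@dataclass
class PipelineConfig:
    """Every numeric cutoff and switch of the pipeline, with field defaults
    exactly the analysis' canonical values."""

    counts_path: str | None = None
    snp_annotation_path: str | None = None
    gene_annotation_path: str | None = None
    dna_counts_path: str | None = None
    output_dir: str | None = None
    p_cutoff: float = 0.01
    min_allele: int = 4
    min_depth: int = 20
    testable_frac: float = 0.20
    min_ratio_samples: int = 10
    hi_freq_quantile: float = 0.75
    exclude_allele_biased: bool = False
    apply_editing_filter: bool = False
    require_known_variant: bool = True
    paired_tests: bool = True
    fdr_mode: bool = False
    snp_mode: str = "any"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_cutoff <= 1.0:
            raise ValidationError("p_cutoff must lie in (0, 1]")
        if self.min_allele < 0 or self.min_depth < 1 or self.min_ratio_samples < 1:
            raise ValidationError("count thresholds must be positive")
        if not 0.0 < self.testable_frac <= 1.0:
            raise ValidationError("testable_frac must lie in (0, 1]")
        if not 0.0 < self.hi_freq_quantile <= 1.0:
            raise ValidationError("hi_freq_quantile must lie in (0, 1]")
        if self.snp_mode not in ("any", "representative"):
            raise ValidationError("snp_mode must be 'any' or 'representative'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)


def write_counts(counts: pd.DataFrame, path) -> Path:
    return write_table(counts[COUNT_COLUMNS], path)


def _validate_counts_frame(counts: pd.DataFrame, path) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad_tissue = ~counts["tissue"].isin(_TISSUES)
    if bad_tissue.any():
        line = int(np.flatnonzero(bad_tissue)[0]) + 2  # header is line 1
        raise ValidationError(f"{path}: invalid tissue value at line {line}")
    for col in ("ref_count", "alt_count", "pos"):
        if not pd.api.types.is_integer_dtype(counts[col]):
            try:
                counts[col] = counts[col].astype(int)
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path}: non-integer values in {col}") from exc
    if (counts[["ref_count", "alt_count"]] < 0).any().any():
        raise ValidationError(f"{path}: negative allele counts")
    same = counts["ref"] == counts["alt"]
    if same.any():
        line = int(np.flatnonzero(same)[0]) + 2
        raise ValidationError(f"{path}: ref equals alt at line {line}")
    return counts


def read_counts(path, format: str | None = None) -> pd.DataFrame:
    """Read allele counts from TSV or VCF (auto-detected by extension)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return read_counts_vcf(path)
    if format != "tsv":
        raise ValidationError(f"unknown counts format {format!r}")
    counts = read_table(path)
    return _validate_counts_frame(counts, path)


def read_counts_vcf(path) -> pd.DataFrame:
    """Allele counts from a VCF 4.2 file with per-sample GT and AD.

    One record per heterozygous (0/1) genotype per sample; other genotypes
    are skipped and their count logged.  The gene is taken from the ``GENE``
    INFO tag; tissue from the sample-name suffix (``-T`` tumor, ``-N``
    adjacent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    n_skipped = 0
    for v in vcf:
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValidationError(
                f"{path}: missing FORMAT/AD at {v.CHROM}:{v.POS}"
            )
        gene = v.INFO.get("GENE", ".")
        for i, s in enumerate(samples):
            if v.gt_types[i] != vcf.HET:
                n_skipped += 1
                continue
            if s.endswith("-T"):
                tissue, patient = "tumor", s[:-2]
            elif s.endswith("-N"):
                tissue, patient = "adjacent", s[:-2]
            else:
                tissue, patient = "tumor", s
            rows.append(
                (
                    s, patient, tissue, v.CHROM, v.POS,
                    v.ID or f"{v.CHROM}:{v.POS}", gene, v.REF, v.ALT[0],
                    int(ad[i][0]), int(ad[i][1]),
                )
            )
    if n_skipped:
        logger.info("read_counts_vcf: skipped %d non-heterozygous genotypes", n_skipped)
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return _validate_counts_frame(counts, path)


def write_vcf_per_patient(counts: pd.DataFrame, directory) -> list:
    """Write one VCF 4.2 per patient with GT=0/1 and AD for each sample."""
    import pysam

    directory = Path(directory)
    written = []
    for patient, sub in counts.groupby("patient_id", sort=True):
        header = pysam.VariantHeader()
        for chrom in sorted(sub["chrom"].unique()):
            header.add_line(f"##contig=<ID={chrom},length=536870911>")
        header.add_line(
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">'
        )
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        header.add_line(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
        )
        sample_ids = sorted(sub["sample_id"].unique())
        for s in sample_ids:
            header.add_sample(s)
        path = directory / f"{patient}.vcf"
        out = pysam.VariantFile(str(path), "w", header=header)
        site_cols = ["chrom", "pos", "snp_id", "gene_id", "ref", "alt"]
        wide = sub.pivot_table(
            index=site_cols, columns="sample_id",
            values=["ref_count", "alt_count"], aggfunc="first",
        )
        wide = wide.reset_index().sort_values(["chrom", "pos"])
        for _, row in wide.iterrows():
            rec = out.new_record(
                contig=row[("chrom", "")],
                start=int(row[("pos", "")]) - 1,
                alleles=(row[("ref", "")], row[("alt", "")]),
                id=row[("snp_id", "")],
            )
            rec.info["GENE"] = row[("gene_id", "")]
            for s in sample_ids:
                rx = row.get(("ref_count", s))
                ax = row.get(("alt_count", s))
                if pd.isna(rx) or pd.isna(ax):
                    continue
                rec.samples[s]["GT"] = (0, 1)
                rec.samples[s]["AD"] = (int(rx), int(ax))
            out.write(rec)
        out.close()
        written.append(path)
    return written


def read_annotations(snp_path, gene_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the SNP and gene annotation tables.

    Unknown consequence strings are mapped to ``other`` with a warning;
    duplicate SNP ids or out-of-range conservation scores are errors.
    dN/dS is recomputed as dn/ds and left missing where ds = 0.
    """
    snp = read_table(snp_path)
    required = {"snp_id", "gene_id", "strand", "consequence", "conservation", "known_variant"}
    missing = required - set(snp.columns)
    if missing:
        raise ValidationError(f"{snp_path}: missing columns {sorted(missing)}")
    if snp["snp_id"].duplicated().any():
        dup = snp.loc[snp["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"{snp_path}: duplicate snp_id {dup!r}")
    cons = snp["conservation"]
    if ((cons < 0) | (cons > 1)).any():
        raise ValidationError(f"{snp_path}: conservation outside [0, 1]")
    unknown = ~snp["consequence"].isin(_CONSEQUENCES)
    if unknown.any():
        logger.warning(
            "read_annotations: %d unknown consequence strings mapped to 'other'",
            int(unknown.sum()),
        )
        snp.loc[unknown, "consequence"] = "other"

    gene = read_table(gene_path)
    gmissing = {"gene_id", "dn", "ds"} - set(gene.columns)
    if gmissing:
        raise ValidationError(f"{gene_path}: missing columns {sorted(gmissing)}")
    if ((gene["dn"] < 0) | (gene["ds"] < 0)).any():
        raise ValidationError(f"{gene_path}: negative substitution rates")
    with np.errstate(divide="ignore", invalid="ignore"):
        gene["dnds"] = np.where(gene["ds"] > 0, gene["dn"] / gene["ds"], np.nan)
    return snp, gene
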