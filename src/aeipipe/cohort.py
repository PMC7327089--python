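"""Cohort-level aggregation of gene-sample AEI calls.

Three summaries drive the downstream comparisons:

* per-sample AEI proportion — the fraction of a sample's testable genes
  called imbalanced (a gene is testable when at least one of its SNPs
  survives the read-count filters);
* per-unit AEI frequency — for a gene or SNP, the fraction of testable
  samples in which it is called imbalanced, reported only for units
  testable in at least 20% of the tissue's cohort;
* major/minor ratio statistics — per gene, the mean and coefficient of
  variation across samples of the (major allele)/(minor allele) read-count
  ratio at the representative SNP, where the major allele is the one more
  often over-expressed across adjacent-tissue samples.  The CV serves as an
  expression-noise measure.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "sample_aei_proportion",
    "sample_aei_proportions",
    "unit_aei_frequency",
    "high_frequency_threshold",
    "high_frequency_units",
    "assign_major_minor",
    "ratio_stats",
]

logger = logging.getLogger(__name__)


def _drop_biased(calls: pd.DataFrame, exclude_biased: bool) -> pd.DataFrame:
    if exclude_biased and "allele_biased" in calls.columns:
        return calls.loc[~calls["allele_biased"].astype(bool)]
    return calls


def sample_aei_proportion(calls: pd.DataFrame, exclude_biased: bool = True) -> dict:
    """AEI proportion for the single sample contained in ``calls``.

    Raises :class:`DegenerateInputError` when no gene is testable, since
    the proportion is then undefined.
    """
    calls = _drop_biased(calls, exclude_biased)
    testable = calls.loc[calls["testable"].astype(bool)]
    if len(testable) == 0:
        raise DegenerateInputError("no testable genes: AEI proportion undefined")
    if testable["sample_id"].nunique() > 1:
        raise ValidationError("expected calls for a single sample")
    n_testable = len(testable)
    n_aei = int(testable["is_aei"].sum())
    return {
        "sample_id": testable["sample_id"].iloc[0],
        "tissue": testable["tissue"].iloc[0] if "tissue" in testable else None,
        "n_testable": n_testable,
        "n_aei": n_aei,
        "proportion": n_aei / n_testable,
    }


def sample_aei_proportions(
    calls: pd.DataFrame, exclude_biased: bool = True
) -> pd.DataFrame:
    """Per-sample AEI proportions across the whole cohort.

    Samples without a single testable gene do not appear.
    """
    calls = _drop_biased(calls, exclude_biased)
    testable = calls.loc[calls["testable"].astype(bool)]
    if len(testable) == 0:
        return pd.DataFrame(
            columns=["sample_id", "patient_id", "tissue", "n_testable", "n_aei", "proportion"]
        )
    keys = [k for k in ("sample_id", "patient_id", "tissue") if k in testable.columns]
    grouped = testable.groupby(keys, sort=True, as_index=False).agg(
        n_testable=("is_aei", "size"), n_aei=("is_aei", "sum")
    )
    grouped["proportion"] = grouped["n_aei"] / grouped["n_testable"]
    return grouped


def unit_aei_frequency(
    calls: pd.DataFrame,
    unit: str,
    cohort_sizes: dict,
    testable_frac: float = 0.20,
    exclude_biased: bool = True,
) -> pd.DataFrame:
    """Per-unit AEI frequency by tissue, under the 20%-of-cohort rule.

    ``unit`` is ``'gene'`` (rows of gene-sample calls) or ``'snp'`` (rows of
    surviving SNP calls).  ``cohort_sizes`` maps tissue to the number of
    samples of that tissue in the cohort; a unit is reported only when
    testable in at least ``ceil(testable_frac * cohort_size)`` samples.
    Frequency is computed over testable samples only: an untestable gene is
    unobserved, not balanced.
    """
    if unit not in ("gene", "snp"):
        raise ValidationError(f"unknown unit {unit!r}")
    id_col = "gene_id" if unit == "gene" else "snp_id"
    calls = _drop_biased(calls, exclude_biased)
    if "testable" in calls.columns:
        calls = calls.loc[calls["testable"].astype(bool)]
    if len(calls) == 0:
        return pd.DataFrame(
            columns=["unit_id", "tissue", "n_testable_samples", "n_aei_samples", "frequency"]
        )
    grouped = calls.groupby([id_col, "tissue"], sort=True, as_index=False).agg(
        n_testable_samples=("is_aei", "size"), n_aei_samples=("is_aei", "sum")
    )
    min_needed = grouped["tissue"].map(
        {t: math.ceil(testable_frac * n) for t, n in cohort_sizes.items()}
    )
    grouped = grouped.loc[grouped["n_testable_samples"] >= min_needed].copy()
    grouped["frequency"] = grouped["n_aei_samples"] / grouped["n_testable_samples"]
    return grouped.rename(columns={id_col: "unit_id"}).reset_index(drop=True)


def high_frequency_threshold(frequencies, quantile: float = 0.75) -> float:
    """Fourth-quartile cut-off for "high-frequency" AEI units.

    The 75th percentile by linear interpolation of order statistics
    (h = (n-1) * 0.75 + 1); units at or above the threshold count as
    high-frequency.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size == 0:
        raise ValidationError("cannot take a quartile of an empty list")
    return float(np.percentile(frequencies, 100 * quantile, method="linear"))


def high_frequency_units(freq_records: pd.DataFrame, quantile: float = 0.75) -> pd.DataFrame:
    """Subset of frequency records at or above the fourth-quartile cut-off,
    computed within each tissue."""
    parts = []
    for tissue, sub in freq_records.groupby("tissue"):
        thr = high_frequency_threshold(sub["frequency"], quantile)
        parts.append(sub.loc[sub["frequency"] >= thr])
    if not parts:
        return freq_records.iloc[0:0]
    return pd.concat(parts, ignore_index=True)


def assign_major_minor(adjacent_calls: pd.DataFrame) -> pd.DataFrame:
    """Designate each gene's major allele from adjacent-tissue samples.

    The major allele is the one with the higher expression fraction in the
    majority of testable adjacent samples; samples at exactly 0.5 count for
    neither side, and exact ties resolve toward the reference allele.
    Genes with no testable adjacent sample are skipped with a warning.
    """
    calls = adjacent_calls.loc[adjacent_calls["testable"].astype(bool)]
    if "tissue" in calls.columns:
        non_adj = calls["tissue"] != "adjacent"
        if non_adj.any():
            raise ValidationError("assign_major_minor expects adjacent-tissue calls only")
    skipped = set(adjacent_calls["gene_id"]) - set(calls["gene_id"])
    if skipped:
        logger.warning(
            "assign_major_minor: %d genes had no testable adjacent sample", len(skipped)
        )
    if len(calls) == 0:
        return pd.DataFrame(columns=["gene_id", "major_allele"])
    rf = calls["ref_fraction"]
    counts = pd.DataFrame(
        {
            "gene_id": calls["gene_id"],
            "ref_up": (rf > 0.5).astype(int),
            "alt_up": (rf < 0.5).astype(int),
        }
    ).groupby("gene_id", sort=True, as_index=False).sum()
    counts["major_allele"] = np.where(counts["ref_up"] >= counts["alt_up"], "ref", "alt")
    return counts[["gene_id", "major_allele"]]


def ratio_stats(
    gene_calls: pd.DataFrame,
    major_map: pd.DataFrame,
    min_samples: int = 10,
    genes=None,
    exclude_biased: bool = True,
) -> pd.DataFrame:
    """Mean and CV of the major/minor count ratio per gene and tissue.

    Ratios use the representative SNP's read counts in each testable sample.
    ``genes`` optionally restricts to a screened set (typically genes called
    AEI in adjacent tissue).  Genes observed in fewer than ``min_samples``
    samples of a tissue are dropped for that tissue.  CV is the sample
    standard deviation (n-1 denominator) divided by the mean.
    """
    calls = _drop_biased(gene_calls, exclude_biased)
    calls = calls.loc[calls["testable"].astype(bool)]
    if genes is not None:
        calls = calls.loc[calls["gene_id"].isin(set(genes))]
    merged = calls.merge(major_map, on="gene_id", how="inner")
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["gene_id", "tissue", "major_allele", "n_samples_used", "mean_ratio", "cv_ratio"]
        )
    is_ref_major = merged["major_allele"] == "ref"
    major = np.where(is_ref_major, merged["rep_ref_count"], merged["rep_alt_count"])
    minor = np.where(is_ref_major, merged["rep_alt_count"], merged["rep_ref_count"])
    if np.any(minor == 0):
        # cannot occur post-filter (both alleles >= 4 reads)
        raise ValidationError("zero minor-allele count in ratio computation")
    merged["ratio"] = major / minor
    out = merged.groupby(["gene_id", "tissue", "major_allele"], sort=True, as_index=False).agg(
        n_samples_used=("ratio", "size"),
        mean_ratio=("ratio", "mean"),
        sd_ratio=("ratio", "std"),  # pandas std is the n-1 (sample) form
    )
    out = out.loc[out["n_samples_used"] >= min_samples].copy()
    out["cv_ratio"] = out["sd_ratio"] / out["mean_ratio"]
    return out.drop(columns="sd_ratio").reset_index(drop=True)
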