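"""Statistical comparisons over cohort summaries.

Covers the comparisons the pipeline reports: paired tumor-vs-adjacent
tests of per-sample AEI proportion, linear-regression associations of AEI
frequency with per-site conservation (phastCons-like scores) and per-gene
dN/dS, mean and CV contrasts of the major/minor allelic ratio, the
synonymous vs non-synonymous consequence contrast, and the A-to-G
RNA-editing site filter applied on the transcribed strand.

All tests are classical: exact paired (or Welch) t-tests via scipy and
ordinary least squares slopes, whose two-sided p-value equals the Pearson
correlation test in simple regression.  No multiplicity correction is
applied across the suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DependencyError, ValidationError

__all__ = [
    "TestResult",
    "paired_t_test",
    "regression_correlation",
    "conservation_association",
    "dnds_association",
    "consequence_groups",
    "editing_site_ids",
    "rna_editing_filter",
    "run_association_suite",
]

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One test's outcome: statistic, df, p, effect summary and sample size."""

    test_name: str
    statistic: float | None = None
    degrees_of_freedom: float | None = None
    p_value: float | None = None
    effect: dict = field(default_factory=dict)
    n: int = 0
    status: str = "ok"
    reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def paired_t_test(x, y, name: str = "paired_t", paired: bool = True) -> TestResult:
    """Two-sided t-test of matched (default) or independent Welch samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and len(x) != len(y):
        raise ValidationError("paired test requires equal-length vectors")
    if min(len(x), len(y)) < 2:
        raise ValidationError("need at least 2 observations per vector")
    if paired:
        d = x - y
        if np.allclose(d.std(ddof=1), 0.0):
            raise DegenerateInputError("zero-variance paired differences")
        t, p = stats.ttest_rel(x, y)
        df = len(d) - 1
        effect = {"mean_difference": float(d.mean())}
        n = len(d)
    else:
        if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
            raise DegenerateInputError("zero variance in both groups")
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = float(res.df)
        effect = {"mean_difference": float(x.mean() - y.mean())}
        n = len(x) + len(y)
    return TestResult(name, float(t), float(df), float(p), effect, n)


def regression_correlation(x, y, name: str = "regression") -> TestResult:
    """Simple OLS of y on x: Pearson r, slope, two-sided p for slope = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.allclose(x.std(), 0.0):
        raise ValidationError("constant predictor")
    fit = stats.linregress(x, y)
    return TestResult(
        name,
        statistic=float(fit.slope / fit.stderr) if fit.stderr > 0 else float("inf"),
        degrees_of_freedom=len(x) - 2,
        p_value=float(fit.pvalue),
        effect={"r": float(fit.rvalue), "slope": float(fit.slope), "intercept": float(fit.intercept)},
        n=len(x),
    )


def conservation_association(
    snp_frequencies: pd.DataFrame, snp_annotation: pd.DataFrame
) -> list[TestResult]:
    """Per-tissue regression of per-site AEI frequency on conservation."""
    merged = snp_frequencies.merge(
        snp_annotation[["snp_id", "conservation"]],
        left_on="unit_id",
        right_on="snp_id",
        how="inner",
    )
    out = []
    for tissue, sub in merged.groupby("tissue", sort=True):
        out.append(
            regression_correlation(
                sub["conservation"], sub["frequency"],
                name=f"conservation_vs_aei_frequency[{tissue}]",
            )
        )
    return out


def dnds_association(
    gene_frequencies: pd.DataFrame, gene_annotation: pd.DataFrame
) -> list[TestResult]:
    """Per-tissue regression of per-gene AEI frequency on dN/dS.

    Genes without a defined dN/dS (ds = 0) are dropped and logged.
    """
    ann = gene_annotation[["gene_id", "dnds"]]
    n_missing = int(ann["dnds"].isna().sum())
    if n_missing:
        logger.info("dnds_association: dropping %d genes without dN/dS", n_missing)
    merged = gene_frequencies.merge(
        ann.dropna(subset=["dnds"]), left_on="unit_id", right_on="gene_id", how="inner"
    )
    out = []
    for tissue, sub in merged.groupby("tissue", sort=True):
        out.append(
            regression_correlation(
                sub["dnds"], sub["frequency"],
                name=f"dnds_vs_aei_frequency[{tissue}]",
            )
        )
    return out


def consequence_groups(
    snp_calls: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Per-sample AEI proportions in non-synonymous vs synonymous genes.

    Within each sample, a gene joins the non-synonymous group when any of
    its surviving SNPs is non-synonymous (presence of an amino-acid-changing
    allele defines exposure) and the synonymous group when all surviving
    SNPs are synonymous; genes whose surviving SNPs are only of other
    consequence join neither.  Samples where either group is empty are
    skipped with a warning.
    """
    merged = snp_calls.merge(
        snp_annotation[["snp_id", "consequence"]], on="snp_id", how="left"
    )
    unknown = merged["consequence"].isna()
    if unknown.any():
        raise ValidationError("annotations must cover all surviving SNPs")
    merged = merged.assign(
        _nonsyn=merged["consequence"] == "nonsynonymous",
        _syn=merged["consequence"] == "synonymous",
        _sig=merged["p_value"] < p_cutoff,
    )
    per_gene = merged.groupby(["sample_id", "tissue", "gene_id"], sort=True).agg(
        any_nonsyn=("_nonsyn", "any"),
        all_syn=("_syn", "all"),
        is_aei=("_sig", "any"),
    ).reset_index()
    rows = []
    for (sample_id, tissue), sub in per_gene.groupby(["sample_id", "tissue"], sort=True):
        grp_a = sub.loc[sub["any_nonsyn"]]
        grp_b = sub.loc[~sub["any_nonsyn"] & sub["all_syn"]]
        if len(grp_a) == 0 or len(grp_b) == 0:
            logger.warning("consequence_groups: sample %s skipped (empty group)", sample_id)
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "tissue": tissue,
                "n_nonsyn_genes": len(grp_a),
                "n_syn_genes": len(grp_b),
                "prop_nonsyn": grp_a["is_aei"].mean(),
                "prop_syn": grp_b["is_aei"].mean(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "tissue", "n_nonsyn_genes", "n_syn_genes", "prop_nonsyn", "prop_syn"],
    )


def editing_site_ids(sites: pd.DataFrame, snp_annotation: pd.DataFrame) -> set:
    """SNP ids whose allele pair reads A/G on the transcribed strand.

    94% of RNA editing is A-to-G, so such sites may be editing artifacts
    rather than genomic SNPs.  On + strand genes the genomic pair {A, G} is
    already the sense pair; on - strand genes the sense pair {A, G} appears
    genomically as {T, C}.  SNPs with unknown strand are retained (and
    counted in a warning) since the call cannot be made.
    """
    sub = sites[["snp_id", "ref", "alt"]].drop_duplicates("snp_id")
    merged = sub.merge(snp_annotation[["snp_id", "strand"]], on="snp_id", how="left")
    unknown = ~merged["strand"].isin(["+", "-"])
    if unknown.any():
        logger.warning(
            "editing filter: %d SNPs with unknown strand retained", int(unknown.sum())
        )
    pair = merged["ref"] + merged["alt"]
    plus_ag = merged["strand"].eq("+") & pair.isin(["AG", "GA"])
    minus_ag = merged["strand"].eq("-") & pair.isin(["TC", "CT"])
    return set(merged.loc[plus_ag | minus_ag, "snp_id"])


def rna_editing_filter(records: pd.DataFrame, snp_annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop records at candidate A-to-G editing sites (sense-strand A/G pairs)."""
    drop = editing_site_ids(records, snp_annotation)
    return records.loc[~records["snp_id"].isin(drop)]


def _patient_paired(proportions: pd.DataFrame, name: str, paired: bool) -> TestResult:
    wide = proportions.pivot_table(
        index="patient_id", columns="tissue", values="proportion"
    ).dropna()
    if not {"tumor", "adjacent"} <= set(wide.columns):
        raise DependencyError("need proportions for both tissues")
    return paired_t_test(wide["tumor"], wide["adjacent"], name=name, paired=paired)


def _gene_paired(ratio_df: pd.DataFrame, value: str, name: str, paired: bool) -> TestResult:
    wide = ratio_df.pivot_table(index="gene_id", columns="tissue", values=value).dropna()
    if not {"tumor", "adjacent"} <= set(wide.columns):
        raise DependencyError("need ratio statistics for both tissues")
    return paired_t_test(wide["tumor"], wide["adjacent"], name=name, paired=paired)


def run_association_suite(
    *,
    proportions: pd.DataFrame,
    snp_frequencies: pd.DataFrame,
    gene_frequencies: pd.DataFrame,
    ratio_statistics: pd.DataFrame,
    snp_calls: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    p_cutoff: float = 0.01,
    paired: bool = True,
    label: str = "",
) -> list[TestResult]:
    """Run the full comparison suite on completed cohort summaries.

    Emits: tumor-vs-adjacent AEI proportion (paired over patients);
    conservation and dN/dS regressions per tissue; mean-ratio and CV
    paired tests over genes; and the consequence contrast per tissue.
    Tests whose preconditions fail are reported with status ``skipped``
    rather than aborting the suite.  ``label`` suffixes test names when the
    suite is re-run on filtered inputs (allele-bias removal, editing filter).
    """
    for arg, argname in (
        (proportions, "proportions"),
        (snp_frequencies, "snp_frequencies"),
        (gene_frequencies, "gene_frequencies"),
        (ratio_statistics, "ratio_statistics"),
        (snp_calls, "snp_calls"),
    ):
        if arg is None:
            raise DependencyError(f"association suite requires {argname}")
    suffix = f"{{{label}}}" if label else ""
    results: list[TestResult] = []

    def attempt(fn, name):
        try:
            res = fn()
        except (ValidationError, DegenerateInputError, DependencyError) as exc:
            results.append(TestResult(name + suffix, status="skipped", reason=str(exc)))
            return
        if isinstance(res, list):
            for r in res:
                r.test_name += suffix
            results.extend(res)
        else:
            res.test_name += suffix
            results.append(res)

    attempt(
        lambda: _patient_paired(proportions, "aei_proportion_tumor_vs_adjacent", paired),
        "aei_proportion_tumor_vs_adjacent",
    )
    attempt(lambda: conservation_association(snp_frequencies, snp_annotation),
            "conservation_vs_aei_frequency")
    attempt(lambda: dnds_association(gene_frequencies, gene_annotation),
            "dnds_vs_aei_frequency")
    attempt(
        lambda: _gene_paired(
            ratio_statistics, "mean_ratio", "mean_ratio_tumor_vs_adjacent", paired
        ),
        "mean_ratio_tumor_vs_adjacent",
    )
    attempt(
        lambda: _gene_paired(
            ratio_statistics, "cv_ratio", "cv_ratio_tumor_vs_adjacent", paired
        ),
        "cv_ratio_tumor_vs_adjacent",
    )

    def consequence_contrasts():
        groups = consequence_groups(snp_calls, snp_annotation, p_cutoff)
        out = []
        for tissue, sub in groups.groupby("tissue", sort=True):
            out.append(
                paired_t_test(
                    sub["prop_nonsyn"], sub["prop_syn"],
                    name=f"nonsyn_vs_syn_proportion[{tissue}]",
                    paired=paired,
                )
            )
        if not out:
            raise DegenerateInputError("no sample had both consequence groups")
        return out

    attempt(consequence_contrasts, "nonsyn_vs_syn_proportion")
    return results
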