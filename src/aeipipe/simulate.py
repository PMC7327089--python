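"""Seeded synthetic paired tumor/adjacent cohorts of allele-specific counts.

The generator emulates the statistical structure that the AEI analyses
assume, with a ground-truth table for parameter-recovery tests:

* per-gene heterozygous SNP counts from a zero-truncated Poisson;
* read depth per SNP and sample from a negative binomial;
* allele counts from a beta-binomial whose intra-class correlation ``rho``
  is tissue-specific (``rho = 0`` is the exact binomial limit), so tumor
  samples can be noisier than adjacent tissue at identical true allelic
  ratio theta;
* a logistic model linking each gene's probability of true AEI to its
  conservation score (negative coefficient: conserved genes imbalanced less
  often) and to carrying non-synonymous SNPs (positive coefficient);
* a log-linear map from conservation to dN/dS, so that selection signatures
  at the site level and the gene level are mutually consistent;
* optional DNA-level allelic bias in tumor (copy-number imbalance proxy)
  and optional artifact sites lacking the known-variant flag, to exercise
  the allele-bias and dbSNP-style filters.

Tumor and adjacent tissue share theta: the generated difference between
tissues is purely one of noise, not of mean allelic ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "draw_allele_counts",
    "assign_gene_truth",
    "simulate_cohort",
    "write_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Generative parameters for a paired cohort.

    Defaults describe a cohort in which roughly a quarter of genes carry a
    true allelic imbalance, with the imbalance probability shaped by
    conservation and consequence, and in which tumor tissue differs from
    adjacent tissue only by a ten-fold larger overdispersion.
    """

    n_pairs: int = 60
    n_genes: int = 2000
    mean_snps_per_gene: float = 1.2
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    alpha_aei: float = 0.0
    beta_cons: float = -4.0
    beta_nonsyn: float = 1.0
    theta_lo: float = 0.65
    theta_hi: float = 0.90
    rho_adjacent: float = 0.005
    rho_tumor: float = 0.05
    frac_nonsyn: float = 0.4
    frac_dna_bias: float = 0.0
    dna_theta: float = 0.7
    dnds_link_a: float = 0.0
    dnds_link_b: float = 2.0
    dnds_link_sd: float = 0.3
    frac_artifact: float = 0.0
    include_dna: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1 or self.n_genes < 0:
            raise ValidationError("n_pairs must be >= 1 and n_genes >= 0")
        for name in ("frac_nonsyn", "frac_dna_bias", "frac_artifact"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("rho_adjacent", "rho_tumor"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if not (0.5 < self.theta_lo <= self.theta_hi <= 1.0):
            raise ValidationError("need 0.5 < theta_lo <= theta_hi <= 1")
        if not (0.0 < self.dna_theta < 1.0):
            raise ValidationError("dna_theta must lie in (0, 1)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValidationError("depth parameters must be positive")
        if self.mean_snps_per_gene < 1.0:
            raise ValidationError("mean_snps_per_gene must be >= 1 (zero-truncated)")
        if self.frac_dna_bias > 0:
            self.include_dna = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth and configuration."""

    counts: pd.DataFrame
    snp_annotation: pd.DataFrame
    gene_annotation: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig
    dna_counts: pd.DataFrame | None = None


def draw_allele_counts(theta, depth, rho, rng):
    """Draw (major, minor) read counts for one or many SNP observations.

    ``theta`` is the expression fraction of the designated major allele.
    With ``rho = 0`` the major count is Binomial(depth, theta); with
    ``rho > 0`` it is beta-binomial with shape parameters
    ``a = theta (1 - rho) / rho`` and ``b = (1 - theta)(1 - rho) / rho``,
    which preserves the mean and inflates the variance by ``1 + (depth-1) rho``.
    """
    theta = np.asarray(theta, dtype=float)
    depth = np.asarray(depth)
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        raise ValidationError("theta must lie in (0, 1)")
    if not 0.0 <= rho < 1.0:
        raise ValidationError("rho must lie in [0, 1)")
    if np.any(depth < 1):
        raise ValidationError("depth must be >= 1")
    if rho == 0.0:
        major = rng.binomial(depth, theta)
    else:
        a = theta * (1.0 - rho) / rho
        b = (1.0 - theta) * (1.0 - rho) / rho
        p = rng.beta(a, b, size=np.broadcast_shapes(theta.shape, depth.shape))
        major = rng.binomial(depth, p)
    return major, depth - major


def _zero_truncated_poisson(mean: float, size: int, rng) -> np.ndarray:
    """Sample a zero-truncated Poisson with the given *truncated* mean.

    The underlying rate lambda solves lambda / (1 - exp(-lambda)) = mean;
    at mean = 1 the distribution degenerates to all ones.
    """
    if size == 0:
        return np.zeros(0, dtype=int)
    if mean <= 1.0 + 1e-9:
        return np.ones(size, dtype=int)
    lam = brentq(lambda L: L / (1.0 - math.exp(-L)) - mean, 1e-12, 2 * mean + 10)
    k = rng.poisson(lam, size)
    zeros = k == 0
    while zeros.any():
        k[zeros] = rng.poisson(lam, int(zeros.sum()))
        zeros = k == 0
    return k


def assign_gene_truth(config: SimulationConfig, rng) -> pd.DataFrame:
    """Draw the per-gene AEI architecture.

    Conservation comes from a bimodal Beta mixture (0.7 Beta(1,3) +
    0.3 Beta(8,2), a phastCons-like shape); the true-AEI indicator from
    P(AEI) = logistic(alpha_aei + beta_cons * conservation
    + beta_nonsyn * 1[non-synonymous]); theta is uniform on
    [theta_lo, theta_hi] for true-AEI genes and exactly 0.5 otherwise.
    ``alpha_aei = -inf`` is an allowed sentinel for probability zero.
    """
    g = config.n_genes
    gene_id = np.array([f"g{i:05d}" for i in range(g)])
    hi_comp = rng.random(g) < 0.3
    conservation = np.where(hi_comp, rng.beta(8, 2, g), rng.beta(1, 3, g))
    nonsyn = rng.random(g) < config.frac_nonsyn
    linpred = config.alpha_aei + config.beta_cons * conservation + config.beta_nonsyn * nonsyn
    p_aei = expit(linpred)
    is_aei = rng.random(g) < p_aei
    theta = np.where(is_aei, rng.uniform(config.theta_lo, config.theta_hi, g), 0.5)
    dnds = np.exp(
        config.dnds_link_a
        - config.dnds_link_b * conservation
        + rng.normal(0.0, config.dnds_link_sd, g)
    )
    dna_biased = rng.random(g) < config.frac_dna_bias
    dna_theta = np.where(dna_biased, config.dna_theta, 0.5)
    major_is_ref = rng.random(g) < 0.5
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "is_aei_truth": is_aei,
            "theta": theta,
            "consequence_class": np.where(nonsyn, "nonsynonymous", "synonymous"),
            "conservation": conservation,
            "dnds": dnds,
            "dna_theta": dna_theta,
            "major_is_ref": major_is_ref,
        }
    )


def _snp_table(config: SimulationConfig, truth: pd.DataFrame, rng) -> pd.DataFrame:
    """Lay out SNPs on genes: positions, alleles, strand, consequence."""
    g = config.n_genes
    n_snps = _zero_truncated_poisson(config.mean_snps_per_gene, g, rng)
    n_artifact = int(round(config.frac_artifact * n_snps.sum()))
    gene_idx = np.repeat(np.arange(g), n_snps)
    if n_artifact > 0 and g > 0:
        gene_idx = np.concatenate([gene_idx, rng.integers(0, g, n_artifact)])
    total = len(gene_idx)
    known = np.ones(total, dtype=int)
    if n_artifact > 0:
        known[total - n_artifact:] = 0
    order = np.argsort(gene_idx, kind="stable")
    gene_idx, known = gene_idx[order], known[order]
    strand_gene = np.where(rng.random(g) < 0.5, "+", "-")
    ref_idx = rng.integers(0, 4, total)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + rng.integers(1, 4, total)) % 4]
    within = np.concatenate([np.arange(c) for c in np.bincount(gene_idx, minlength=g)]) if total else np.zeros(0, int)
    chrom = np.array([f"chr{(i % 22) + 1}" for i in gene_idx])
    pos = (gene_idx // 22 + 1) * 100_000 + within * 150 + 1
    snp = pd.DataFrame(
        {
            "snp_id": [f"s{i:06d}" for i in range(total)],
            "gene_id": truth["gene_id"].to_numpy()[gene_idx] if total else np.array([], dtype=object),
            "chrom": chrom,
            "pos": pos.astype(int) if total else pos,
            "ref": ref,
            "alt": alt,
            "strand": strand_gene[gene_idx] if total else np.array([], dtype=object),
            "consequence": truth["consequence_class"].to_numpy()[gene_idx] if total else np.array([], dtype=object),
            "known_variant": known,
            "conservation": truth["conservation"].to_numpy()[gene_idx] if total else np.array([]),
            "_gene_idx": gene_idx,
        }
    )
    return snp


def _draw_tissue_counts(
    snp: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    tissue: str,
    rho: float,
    theta_gene: np.ndarray,
    rng,
) -> pd.DataFrame:
    """Long-format allele counts for one tissue across all pairs."""
    s, n = len(snp), config.n_pairs
    gene_idx = snp["_gene_idx"].to_numpy()
    theta_snp = theta_gene[gene_idx] if s else np.zeros(0)
    major_is_ref = truth["major_is_ref"].to_numpy()[gene_idx] if s else np.zeros(0, bool)
    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    depth = np.maximum(rng.negative_binomial(config.depth_dispersion, p_nb, (n, s)), 1)
    theta_full = np.broadcast_to(theta_snp, (n, s))
    major, minor = draw_allele_counts(theta_full, depth, rho, rng) if s else (depth, depth)
    ref_count = np.where(major_is_ref, major, minor)
    alt_count = np.where(major_is_ref, minor, major)
    suffix = "T" if tissue == "tumor" else "N"
    patient = np.repeat([f"P{i:04d}" for i in range(n)], s)
    return pd.DataFrame(
        {
            "sample_id": np.char.add(patient.astype(str), f"-{suffix}"),
            "patient_id": patient,
            "tissue": tissue,
            "chrom": np.tile(snp["chrom"].to_numpy(), n),
            "pos": np.tile(snp["pos"].to_numpy(), n),
            "snp_id": np.tile(snp["snp_id"].to_numpy(), n),
            "gene_id": np.tile(snp["gene_id"].to_numpy(), n),
            "ref": np.tile(snp["ref"].to_numpy(), n),
            "alt": np.tile(snp["alt"].to_numpy(), n),
            "ref_count": ref_count.ravel(),
            "alt_count": alt_count.ravel(),
        }
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full paired cohort deterministically from ``config.seed``.

    Adjacent and tumor counts share each gene's theta and differ only in
    overdispersion (``rho_adjacent`` vs ``rho_tumor``).  When DNA counts are
    requested, tumor DNA is drawn at each gene's ``dna_theta`` (0.5 unless
    copy-number biased) and adjacent DNA at exactly 0.5, both binomially.
    """
    rng = np.random.default_rng(config.seed)
    truth = assign_gene_truth(config, rng)
    snp = _snp_table(config, truth, rng)
    theta = truth["theta"].to_numpy()
    frames = [
        _draw_tissue_counts(snp, truth, config, "adjacent", config.rho_adjacent, theta, rng),
        _draw_tissue_counts(snp, truth, config, "tumor", config.rho_tumor, theta, rng),
    ]
    counts = pd.concat(frames, ignore_index=True)
    dna = None
    if config.include_dna:
        # DNA carries no expression noise: rho = 0; only copy-number bias
        # (dna_theta != 0.5) separates it from a fair coin.
        dna_theta = truth["dna_theta"].to_numpy()
        half = np.full(config.n_genes, 0.5)
        dna_frames = [
            _draw_tissue_counts(snp, truth, config, "adjacent", 0.0, half, rng),
            _draw_tissue_counts(snp, truth, config, "tumor", 0.0, dna_theta, rng),
        ]
        dna = pd.concat(dna_frames, ignore_index=True)
    snp_annotation = snp[
        ["snp_id", "gene_id", "strand", "consequence", "conservation", "known_variant"]
    ].copy()
    ds = rng.uniform(0.005, 0.2, config.n_genes)
    gene_annotation = pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "dn": truth["dnds"].to_numpy() * ds,
            "ds": ds,
            "dnds": truth["dnds"],
        }
    )
    return SyntheticCohort(
        counts=counts,
        snp_annotation=snp_annotation,
        gene_annotation=gene_annotation,
        truth=truth,
        config=config,
        dna_counts=dna,
    )


def write_cohort(cohort: SyntheticCohort, directory, vcf: bool = False) -> list:
    """Write the cohort as the pipeline's TSV file set (optionally VCFs).

    Emits counts.tsv, snp_annotation.tsv, gene_annotation.tsv, truth.tsv and,
    when DNA counts exist, dna_counts.tsv.  Returns the written paths.
    """
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    written.append(_io.write_counts(cohort.counts, directory / "counts.tsv"))
    if cohort.dna_counts is not None:
        written.append(_io.write_counts(cohort.dna_counts, directory / "dna_counts.tsv"))
    written.append(
        _io.write_table(cohort.snp_annotation, directory / "snp_annotation.tsv")
    )
    written.append(
        _io.write_table(cohort.gene_annotation, directory / "gene_annotation.tsv")
    )
    written.append(_io.write_table(cohort.truth, directory / "truth.tsv"))
    if vcf:
        written.extend(_io.write_vcf_per_patient(cohort.counts, directory))
    return written
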