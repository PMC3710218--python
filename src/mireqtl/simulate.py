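"""Synthetic liver-cohort generator with recorded ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* biallelic SNP genotypes drawn from Hardy-Weinberg proportions over a
  realistic MAF spectrum, with an optional subset of SNPs violating HWE
  through a heterozygote deficit (the direction of genotyping-error
  artifacts);
* miRNA expression built from planted trans-eQTL effects, hidden sample-level
  factors, Gaussian noise, and completely-at-random missingness, with a
  separate block of low-quality features whose heavy missingness fails the
  expressed call;
* mRNA expression built from planted negative miRNA -> mRNA regulation
  effects plus noise;
* an annotation catalog whose entries partially overlap the planted eQTL
  SNPs (those entries carry the alt allele as risk allele) with evidence
  levels drawn uniformly from {1, 2, 3}.

Every planted effect, factor loading and score is recorded in a
:class:`TruthSet`. All four generators are deterministic given the config
seed; each stage derives its own independent random stream from it.

Defaults mirror the study conditions the pipeline targets: 79 samples, 277
expressed miRNAs (of 850 probed), a scaled-down mRNA panel, 4 hidden
factors, and negative regulation effects drawn from a Normal(-1.21, 1.05^2)
truncated to negative values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import SNP_COLUMNS, ExpressionMatrix, GenotypeMatrix, ValidationError, compute_maf
from .core import MIRNA, MRNA, make_catalog

logger = logging.getLogger(__name__)

BetaSampler = Callable[[np.random.Generator, int], np.ndarray]


def normal_beta_sampler(mean: float, sd: float) -> BetaSampler:
    return lambda rng, size: rng.normal(mean, sd, size)


def truncated_negative_normal_sampler(mean: float = -1.21, sd: float = 1.05) -> BetaSampler:
    """Normal(mean, sd^2) truncated to strictly negative values, by rejection."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.normal(mean, sd, size - filled)
            draw = draw[draw < 0]
            out[filled:filled + len(draw)] = draw
            filled += len(draw)
        return out

    return sample


@dataclass
class SimulationConfig:
    """Cohort-generator parameters; defaults are the study conditions."""

    n_samples: int = 79
    n_snps: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_mirnas: int = 277
    n_low_quality_mirnas: int = 573  # probed-but-unexpressed features
    low_quality_missing_rate: float = 0.6
    n_mrnas: int = 2000
    n_planted_eqtls: int = 20  # planted eQTL SNPs
    mirnas_per_eqtl: int = 1  # planted target miRNAs per eQTL SNP
    eqtl_beta_sampler: BetaSampler = field(default_factory=lambda: normal_beta_sampler(1.0, 0.25))
    n_planted_regulations: int = 50
    regulation_beta_sampler: BetaSampler = field(
        default_factory=truncated_negative_normal_sampler)
    n_hidden_factors: int = 4
    factor_sd: float = 1.0
    noise_sd: float = 1.0
    missingness_rate: float = 0.05
    n_hwe_violating_snps: int = 0
    het_deficit: float = 0.1  # heterozygote probability multiplier for HWE violators
    catalog_size: int = 100
    catalog_fraction_overlapping: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_mirnas", "n_low_quality_mirnas",
                     "n_mrnas", "n_planted_eqtls", "n_planted_regulations",
                     "n_hidden_factors", "n_hwe_violating_snps", "catalog_size"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.missingness_rate < 1):
            raise ValidationError("missingness_rate must be in [0, 1)")
        if not (0 <= self.catalog_fraction_overlapping <= 1):
            raise ValidationError("catalog_fraction_overlapping must be in [0, 1]")
        if not (0 < self.maf_low < self.maf_high <= 0.5):
            raise ValidationError("require 0 < maf_low < maf_high <= 0.5")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent random stream for a pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


_STAGE_GENOTYPES, _STAGE_MIRNAS, _STAGE_MRNAS, _STAGE_CATALOG = range(4)


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator, for recovery tests."""

    planted_eqtls: pd.DataFrame  # snp_id, mirna_id, beta
    planted_regulations: pd.DataFrame  # mirna_id, mrna_id, beta
    factor_loadings: pd.DataFrame  # feature x factor
    factor_scores: pd.DataFrame  # sample x factor
    seed: int
    mirna_latent: pd.DataFrame | None = None  # pre-missingness miRNA values


def _empty_truth(seed: int) -> TruthSet:
    return TruthSet(
        planted_eqtls=pd.DataFrame(columns=["snp_id", "mirna_id", "beta"]),
        planted_regulations=pd.DataFrame(columns=["mirna_id", "mrna_id", "beta"]),
        factor_loadings=pd.DataFrame(),
        factor_scores=pd.DataFrame(),
        seed=seed,
    )


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Sample genotypes from Hardy-Weinberg proportions over the MAF spectrum.

    ``n_hwe_violating_snps`` SNPs are instead drawn with their heterozygote
    probability multiplied by ``het_deficit`` and renormalized.
    """
    if cfg.n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    if cfg.n_hwe_violating_snps > cfg.n_snps:
        raise ValidationError("n_hwe_violating_snps exceeds n_snps")
    rng = cfg.rng(_STAGE_GENOTYPES)
    f = rng.uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
    probs = np.column_stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    if cfg.n_hwe_violating_snps:
        viol = rng.choice(cfg.n_snps, cfg.n_hwe_violating_snps, replace=False)
        probs[viol, 1] *= cfg.het_deficit
        probs[viol] /= probs[viol].sum(axis=1, keepdims=True)
    u = rng.random((cfg.n_samples, cfg.n_snps))
    cum = probs.cumsum(axis=1)
    dosage = (u[:, :, None] > cum[None, :, :2]).sum(axis=2).astype(float)

    snp_ids = [f"rs{i + 1}" for i in range(cfg.n_snps)]
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, cfg.n_snps)
    alt = (ref + rng.integers(1, 4, cfg.n_snps)) % 4
    snps = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": [str(i % 22 + 1) for i in range(cfg.n_snps)],
        "pos": (np.arange(cfg.n_snps) // 22 + 1) * 1000,
        "ref_allele": bases[ref],
        "alt_allele": bases[alt],
        "maf": np.nan,
        "hwe_p": np.nan,
    })[SNP_COLUMNS]
    g = GenotypeMatrix(pd.DataFrame(dosage, index=sample_ids, columns=snp_ids), snps)
    return compute_maf(g)


def simulate_mirnas(g: GenotypeMatrix, cfg: SimulationConfig) -> tuple[ExpressionMatrix, TruthSet]:
    """miRNA expression from planted eQTL effects, hidden factors and noise.

    miRNA_j(s) = sum_k beta_jk * dosage_sk + sum_f lambda_jf * F_sf + eps,
    eps ~ N(0, noise_sd^2), factor scores F ~ N(0, factor_sd^2), loadings
    lambda ~ N(0, 1). Missingness is applied uniformly at ``missingness_rate``
    to the expressed block and at ``low_quality_missing_rate`` to the
    low-quality block.
    """
    n_pairs = cfg.n_planted_eqtls * cfg.mirnas_per_eqtl
    if n_pairs > cfg.n_snps * cfg.n_mirnas:
        raise ValidationError("planted eQTL count exceeds n_snps * n_mirnas")
    if cfg.n_planted_eqtls > cfg.n_snps:
        raise ValidationError("n_planted_eqtls exceeds n_snps")
    if cfg.mirnas_per_eqtl > max(cfg.n_mirnas, 1):
        raise ValidationError("mirnas_per_eqtl exceeds n_mirnas")
    rng = cfg.rng(_STAGE_MIRNAS)
    n, m = g.n_samples, cfg.n_mirnas
    mirna_ids = [f"miR-{i + 1}" for i in range(m)]
    lq_ids = [f"miR-lq-{i + 1}" for i in range(cfg.n_low_quality_mirnas)]

    values = np.zeros((m, n))
    eqtl_rows = []
    if cfg.n_planted_eqtls and m:
        snp_idx = rng.choice(g.n_snps, cfg.n_planted_eqtls, replace=False)
        D = g.dosage.to_numpy(dtype=float)
        mir_pool = rng.permutation(m)
        betas = cfg.eqtl_beta_sampler(rng, cfg.n_planted_eqtls * cfg.mirnas_per_eqtl)
        b_i = 0
        for si in snp_idx:
            targets = mir_pool[rng.choice(m, cfg.mirnas_per_eqtl, replace=False)] \
                if cfg.mirnas_per_eqtl > 1 else [mir_pool[b_i % m]]
            for mj in targets:
                beta = betas[b_i]
                b_i += 1
                values[mj] += beta * np.nan_to_num(D[:, si])
                eqtl_rows.append((g.snp_ids[si], mirna_ids[mj], float(beta)))

    k = cfg.n_hidden_factors
    scores = rng.normal(0.0, cfg.factor_sd, (n, k)) if k else np.empty((n, 0))
    loadings = rng.normal(0.0, 1.0, (m, k)) if k else np.empty((m, 0))
    values += loadings @ scores.T
    values += rng.normal(0.0, cfg.noise_sd, (m, n))

    latent = pd.DataFrame(values.copy(), index=mirna_ids, columns=g.sample_ids)
    mask = rng.random((m, n)) < cfg.missingness_rate
    values[mask] = np.nan

    if cfg.n_low_quality_mirnas:
        lq = rng.normal(0.0, cfg.noise_sd, (cfg.n_low_quality_mirnas, n))
        lq[rng.random(lq.shape) < cfg.low_quality_missing_rate] = np.nan
        values = np.vstack([values, lq])

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=mirna_ids + lq_ids, columns=g.sample_ids), MIRNA
    )
    truth = TruthSet(
        planted_eqtls=pd.DataFrame(eqtl_rows, columns=["snp_id", "mirna_id", "beta"]),
        planted_regulations=pd.DataFrame(columns=["mirna_id", "mrna_id", "beta"]),
        factor_loadings=pd.DataFrame(loadings, index=mirna_ids,
                                     columns=[f"factor{i + 1}" for i in range(k)]),
        factor_scores=pd.DataFrame(scores, index=g.sample_ids,
                                   columns=[f"factor{i + 1}" for i in range(k)]),
        seed=cfg.seed,
        mirna_latent=latent,
    )
    return expr, truth


def simulate_mrnas(
    mirna: ExpressionMatrix, cfg: SimulationConfig,
    truth: TruthSet | None = None,
    focal_mrna_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, TruthSet]:
    """mRNA expression from planted negative miRNA regulation plus noise.

    mRNA_i(s) = sum_j gamma_ij * miRNA_j(s) + eta, with gamma < 0 drawn from
    ``regulation_beta_sampler`` for the planted pairs. The latent
    (pre-missingness) miRNA values recorded in ``truth`` are used when
    available. ``focal_mrna_ids`` routes the planted regulations onto a
    designated gene set (one planted pair per focal gene, cycling through the
    regulation count); otherwise target genes are drawn at random.
    """
    rng = cfg.rng(_STAGE_MRNAS)
    n = mirna.n_samples
    mrna_ids = [f"gene{i + 1}" for i in range(cfg.n_mrnas)]
    if truth is not None and truth.mirna_latent is not None:
        src = truth.mirna_latent
    else:
        src = mirna.values.apply(lambda r: r.fillna(r.mean()), axis=1)
    expressed = [f for f in src.index if not f.startswith("miR-lq-")]
    if cfg.n_planted_regulations and not expressed:
        raise ValidationError("no expressed miRNAs to plant regulations on")

    values = rng.normal(0.0, cfg.noise_sd, (cfg.n_mrnas, n))
    reg_rows = []
    if cfg.n_planted_regulations:
        if cfg.n_planted_regulations > cfg.n_mrnas * len(expressed):
            raise ValidationError("planted regulation count exceeds pair space")
        if focal_mrna_ids is not None:
            unknown = [g for g in focal_mrna_ids if g not in set(mrna_ids)]
            if unknown:
                raise ValidationError(f"focal mRNA ids not in matrix: {unknown[:5]}")
            targets = [focal_mrna_ids[i % len(focal_mrna_ids)]
                       for i in range(cfg.n_planted_regulations)]
        else:
            targets = [mrna_ids[i] for i in
                       rng.choice(cfg.n_mrnas, cfg.n_planted_regulations,
                                  replace=cfg.n_planted_regulations > cfg.n_mrnas)]
        gammas = cfg.regulation_beta_sampler(rng, cfg.n_planted_regulations)
        if (gammas >= 0).any():
            raise ValidationError("regulation betas must be strictly negative")
        mir_choice = rng.integers(0, len(expressed), cfg.n_planted_regulations)
        idx = {gid: i for i, gid in enumerate(mrna_ids)}
        for gene, gamma, mi in zip(targets, gammas, mir_choice):
            mir_id = expressed[mi]
            values[idx[gene]] += gamma * src.loc[mir_id].to_numpy()
            reg_rows.append((mir_id, gene, float(gamma)))

    expr = ExpressionMatrix(pd.DataFrame(values, index=mrna_ids,
                                         columns=mirna.sample_ids), MRNA)
    out_truth = TruthSet(
        planted_eqtls=truth.planted_eqtls if truth is not None
        else pd.DataFrame(columns=["snp_id", "mirna_id", "beta"]),
        planted_regulations=pd.DataFrame(reg_rows,
                                         columns=["mirna_id", "mrna_id", "beta"]),
        factor_loadings=truth.factor_loadings if truth is not None else pd.DataFrame(),
        factor_scores=truth.factor_scores if truth is not None else pd.DataFrame(),
        seed=cfg.seed,
        mirna_latent=truth.mirna_latent if truth is not None else None,
    )
    return expr, out_truth


def simulate_catalog(g: GenotypeMatrix, truth: TruthSet, cfg: SimulationConfig) -> pd.DataFrame:
    """Annotation catalog with a controlled overlap with planted eQTL SNPs.

    ``catalog_fraction_overlapping`` of the entries are planted eQTL SNPs
    (risk allele set to the alt allele); the rest are drawn uniformly from
    non-planted SNPs. Evidence levels are uniform over {1, 2, 3}.
    """
    rng = cfg.rng(_STAGE_CATALOG)
    planted = list(dict.fromkeys(truth.planted_eqtls["snp_id"]))
    n_overlap = int(round(cfg.catalog_fraction_overlapping * cfg.catalog_size))
    if n_overlap > len(planted):
        raise ValidationError(
            f"requested overlap {n_overlap} exceeds planted eQTL SNP count {len(planted)}"
        )
    others = [s for s in g.snp_ids if s not in set(planted)]
    n_other = cfg.catalog_size - n_overlap
    if n_other > len(others):
        raise ValidationError("catalog_size exceeds available non-planted SNPs")
    chosen_overlap = list(rng.choice(planted, n_overlap, replace=False)) if n_overlap else []
    chosen_other = list(rng.choice(others, n_other, replace=False)) if n_other else []
    rows = []
    for i, sid in enumerate(chosen_overlap + chosen_other):
        is_planted = i < n_overlap
        rows.append({
            "snp_id": sid,
            "annotation": f"trait_{rng.integers(1, 40)}",
            "risk_allele": g.snps.loc[sid, "alt_allele"] if is_planted else pd.NA,
            "evidence_level": int(rng.integers(1, 4)),
            "source": "synthetic",
        })
    return make_catalog(pd.DataFrame(rows))


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    catalog: pd.DataFrame
    truth: TruthSet


def simulate_cohort(cfg: SimulationConfig,
                    focal_mrna_ids: list[str] | None = None) -> SyntheticCohort:
    """Run all four generators in sequence with one config."""
    g = simulate_genotypes(cfg)
    mirna, truth = simulate_mirnas(g, cfg)
    mrna, truth = simulate_mrnas(mirna, cfg, truth, focal_mrna_ids=focal_mrna_ids)
    catalog = simulate_catalog(g, truth, cfg) if cfg.catalog_size else make_catalog(
        pd.DataFrame(columns=["snp_id", "annotation"]))
    return SyntheticCohort(g, mirna, mrna, catalog, truth)
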