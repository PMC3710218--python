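"""Expression QC, SNP filtering, genotype PCs, and hidden-factor removal.

Order of operations upstream of the association scans:

1. ``call_expressed`` — keep features quantified in at least 75% of samples.
2. ``log2_transform`` / ``quantile_normalize`` — put phenotypes on the scale
   the regressions assume (miRNAs log2; mRNAs quantile-normalized).
3. ``filter_snps`` — MAF strictly above 0.15 and Hardy-Weinberg exact-test
   p >= 0.001 (heterozygote-deficit artifacts fail this).
4. ``genotype_pcs`` — top principal components of the genotype matrix, used
   as ancestry covariates.
5. ``remove_hidden_factors`` — PCA-estimated latent expression factors
   (k = 4 by default) regressed out of every feature, returning residual
   phenotypes robust to unmodelled technical/physiological structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GenotypeMatrix,
    ValidationError,
    compute_maf,
    genotype_counts,
)

logger = logging.getLogger(__name__)


def call_expressed(e: ExpressionMatrix, min_frac: float = 0.75) -> ExpressionMatrix:
    """Retain features with a non-missing fraction >= ``min_frac``."""
    if not (0 < min_frac <= 1):
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    frac = e.values.notna().mean(axis=1)
    keep = frac >= min_frac
    logger.info("call_expressed: retained %d / %d features (min_frac=%.3g)",
                int(keep.sum()), len(keep), min_frac)
    if not keep.any():
        logger.warning("call_expressed: no feature passed the %.3g threshold", min_frac)
    return ExpressionMatrix(e.values.loc[keep].copy(), e.kind)


def log2_transform(e: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Apply value -> log2(value + offset); missing values stay missing."""
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    shifted = e.values + offset
    bad = (shifted <= 0).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-positive value {e.values.iat[i, j]!r} (offset {offset}) at feature "
            f"{e.values.index[i]!r}, sample {e.values.columns[j]!r}"
        )
    return ExpressionMatrix(np.log2(shifted), e.kind)


def quantile_normalize(e: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the mean order-statistic distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; ties within a sample receive the average of the
    reference values over the tied ranks. Idempotent; rejects matrices with
    missing values.
    """
    vals = e.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("quantile_normalize requires a complete matrix")
    ref = np.sort(vals, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average reference values over tied ranks
        ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ser.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=e.values.index, columns=e.values.columns), e.kind
    )


@lru_cache(maxsize=100_000)
def _hwe_weights(n: int, n_rare: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Integer weights of the Levene-Haldane conditional distribution.

    Given ``n`` diploid individuals carrying ``n_rare`` copies of the rarer
    allele, the probability of observing ``h`` heterozygotes is proportional
    to the number of genotype arrangements ``C(n, h) * C(n - h, n_hom_rare) *
    2**h``. Returns (het_counts, weights), exact integers.
    """
    hets = tuple(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    weights = []
    for h in hets:
        hom_rare = (n_rare - h) // 2
        weights.append(math.comb(n, h) * math.comb(n - h, hom_rare) * (1 << h))
    return hets, tuple(weights)


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact Hardy-Weinberg test (Levene-Haldane conditional distribution).

    Two-sided by the probability-mass rule: conditional on the allele counts,
    sum the probabilities of every heterozygote count whose probability does
    not exceed that of the observed count. Computed with exact integer
    arithmetic. Monomorphic SNPs return p = 1 by convention.
    """
    for c in (n_ref_hom, n_het, n_alt_hom):
        if c < 0 or int(c) != c:
            raise ValidationError("genotype counts must be non-negative integers")
    n = n_ref_hom + n_het + n_alt_hom
    if n < 1:
        raise ValidationError("at least one genotyped sample required")
    n_alt = n_het + 2 * n_alt_hom
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    hets, weights = _hwe_weights(n, n_rare)
    w_obs = weights[hets.index(n_het)]
    num = sum(w for w in weights if w <= w_obs)
    return float(num / sum(weights))


def hwe_test_genotypes(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill ``hwe_p`` for every SNP from its hard-call genotype counts."""
    counts = genotype_counts(g)
    g.snps["hwe_p"] = [
        hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else np.nan
        for a, b, c in counts.itertuples(index=False)
    ]
    return g


def filter_snps(g: GenotypeMatrix, maf_min: float = 0.15,
                hwe_alpha: float = 0.001) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly greater than ``maf_min`` and HWE exact-test
    p >= ``hwe_alpha``. MAF and HWE p-values are (re)computed if absent."""
    if g.snps["maf"].isna().all():
        compute_maf(g)
    if g.snps["hwe_p"].isna().all():
        hwe_test_genotypes(g)
    maf_ok = g.snps["maf"] > maf_min
    hwe_ok = g.snps["hwe_p"] >= hwe_alpha
    keep = (maf_ok & hwe_ok).fillna(False)
    logger.info(
        "filter_snps: %d / %d retained (%d failed maf<=%.3g, %d failed hwe p<%.3g)",
        int(keep.sum()), len(keep), int((~maf_ok.fillna(False)).sum()),
        maf_min, int((~hwe_ok.fillna(False)).sum()), hwe_alpha,
    )
    if not keep.any():
        logger.warning("filter_snps: no SNP passed the filters")
    return g.subset_snps(g.snps.index[keep])


def _top_pcs(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k PC scores and loadings of a samples x variables matrix whose
    columns are already centered. Sign fixed so each component's
    largest-magnitude loading is positive."""
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    return u * s, vt.T  # scores (n x k), loadings (p x k)


def genotype_pcs(g: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal components of the sample x SNP matrix.

    Missing dosages are mean-imputed per SNP for this computation only; each
    SNP is centered and scaled to unit variance (constant SNPs dropped).
    Deterministic up to the fixed sign convention.
    """
    if k >= g.n_samples:
        raise ValidationError(f"k={k} must be < n_samples={g.n_samples}")
    vals = g.dosage.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=0)
    vals = np.where(np.isnan(vals), mean, vals)
    vals = vals - mean
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    vals = vals[:, keep] / sd[keep]
    if vals.shape[1] == 0:
        scores = np.zeros((g.n_samples, k))
    else:
        scores, _ = _top_pcs(vals, k)
        if scores.shape[1] < k:
            scores = np.pad(scores, ((0, 0), (0, k - scores.shape[1])))
    return pd.DataFrame(scores, index=g.dosage.index,
                        columns=[f"PC{i + 1}" for i in range(k)])


@dataclass
class FactorAdjustment:
    """Diagnostics of hidden-factor removal."""

    k: int
    factor_scores: pd.DataFrame  # sample x k
    per_feature_correlation: pd.Series  # pre/post correlation per feature

    @property
    def median_correlation(self) -> float:
        return float(self.per_feature_correlation.median())


def remove_hidden_factors(
    e: ExpressionMatrix, k: int = 4, covariates: pd.DataFrame | None = None
) -> tuple[ExpressionMatrix, FactorAdjustment]:
    """Estimate k latent expression factors and return per-feature residuals.

    Factors are the top-k principal components of the feature-centered
    expression matrix (missing values mean-imputed, and supplied covariates
    regressed out, for the estimation step only). Each feature is then
    regressed on the factor scores over its complete cases and replaced by
    its residuals; the per-feature correlation between pre- and
    post-adjustment values is reported as a diagnostic.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k == 0:
        adj = FactorAdjustment(0, pd.DataFrame(index=e.values.columns),
                               pd.Series(dtype=float))
        return ExpressionMatrix(e.values.copy(), e.kind), adj
    if k >= e.n_samples:
        raise ValidationError(f"k={k} must be < n_samples={e.n_samples}")

    vals = e.values.to_numpy(dtype=float)  # features x samples
    feat_mean = np.nanmean(vals, axis=1, keepdims=True)
    filled = np.where(np.isnan(vals), feat_mean, vals)
    mat = (filled - filled.mean(axis=1, keepdims=True)).T  # samples x features
    if covariates is not None:
        C = np.column_stack([np.ones(mat.shape[0]),
                             covariates.loc[e.values.columns].to_numpy(float)])
        mat = mat - C @ np.linalg.lstsq(C, mat, rcond=None)[0]
    scores, _ = _top_pcs(mat, k)
    F = np.column_stack([np.ones(scores.shape[0]), scores])

    resid = np.full_like(vals, np.nan)
    corr = np.full(vals.shape[0], np.nan)
    for i in range(vals.shape[0]):
        obs = ~np.isnan(vals[i])
        y = vals[i, obs]
        Fi = F[obs]
        coef = np.linalg.lstsq(Fi, y, rcond=None)[0]
        r = y - Fi @ coef
        resid[i, obs] = r
        if y.std() > 0 and r.std() > 0:
            corr[i] = np.corrcoef(y, r)[0, 1]
    adj = FactorAdjustment(
        k,
        pd.DataFrame(scores, index=e.values.columns,
                     columns=[f"factor{i + 1}" for i in range(k)]),
        pd.Series(corr, index=e.values.index, name="pre_post_correlation"),
    )
    out = ExpressionMatrix(
        pd.DataFrame(resid, index=e.values.index, columns=e.values.columns), e.kind
    )
    logger.info("remove_hidden_factors: k=%d, median pre/post correlation %.3f",
                k, adj.median_correlation)
    return out, adj
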