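"""Linear-regression association scans and multiple-testing machinery.

Two scans share one OLS engine:

* ``mirna_mrna_scan`` — every (miRNA, mRNA) pair, slope of mRNA on miRNA on
  pairwise-complete observations. Records are partitioned by the sign of the
  slope and Benjamini-Hochberg q-values are computed within the negative
  partition (the biologically expected direction of miRNA repression).
* ``eqtl_scan`` — every (SNP, miRNA) pair, slope of miRNA expression on
  alt-allele dosage. Candidate covariates (age, sex, genotype PCs) are
  screened per miRNA by marginal regression and included when marginally
  associated at ``covariate_screen_alpha``.

Both produce tables with columns ``x_id, y_id, beta, se, t, p, n, q``; the
p-value is two-sided from the t distribution with n - p_model degrees of
freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)


def _t_pvalue(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(p <= 0, _TINY_P, np.minimum(p, 1.0))


def linear_assoc(
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    x_id: str = "x",
    y_id: str = "y",
) -> dict:
    """OLS of y on (intercept, x, covariates); complete-case observations.

    Returns a record dict with the slope, its standard error, t statistic,
    two-sided p-value, and the complete-case n. A constant x (after
    complete-case restriction) or an n below ``p_model + 1`` yields a record
    with NaN statistics, logged and skipped by the scans.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    obs = ~(np.isnan(x) | np.isnan(y) | np.isnan(C).any(axis=1))
    x, y, C = x[obs], y[obs], C[obs]
    n = len(x)
    p_model = 2 + C.shape[1]
    record = {"x_id": x_id, "y_id": y_id, "beta": np.nan, "se": np.nan,
              "t": np.nan, "p": np.nan, "n": n, "q": np.nan}
    if n < p_model + 1:
        logger.debug("linear_assoc(%s, %s): n=%d too small, skipped", x_id, y_id, n)
        return record
    if np.ptp(x) == 0:
        logger.debug("linear_assoc(%s, %s): constant x, skipped", x_id, y_id)
        return record
    if C.shape[1] == 0:
        xc = x - x.mean()
        yc = y - y.mean()
    else:
        X0 = np.column_stack([np.ones(n), C])
        xc = x - X0 @ np.linalg.lstsq(X0, x, rcond=None)[0]
        yc = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        if np.sqrt(xc @ xc) <= 1e-12 * np.sqrt(x @ x):
            logger.debug("linear_assoc(%s, %s): x collinear with covariates", x_id, y_id)
            return record
    sxx = xc @ xc
    sxy = xc @ yc
    beta = sxy / sxx
    sse = max(yc @ yc - beta * sxy, 0.0)
    df = n - p_model
    se = np.sqrt(sse / df / sxx) if df > 0 else np.nan
    if se == 0:
        record.update(beta=beta, se=se, t=np.inf, p=_TINY_P)
        return record
    t = beta / se
    record.update(beta=float(beta), se=float(se), t=float(t),
                  p=float(_t_pvalue(np.array([t]), np.array([df]))[0]))
    return record


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; order-preserving in p.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pairwise_simple_ols(x: np.ndarray, Y: np.ndarray):
    """Vectorized simple OLS of every row of Y on x, pairwise-complete.

    x: (n,) predictor with NaN allowed; Y: (m, n) responses with NaN allowed.
    Returns arrays (beta, se, t, p, n) of length m; rows with n < 4 or a
    constant predictor get NaN statistics.
    """
    W = (~np.isnan(x)) & (~np.isnan(Y))
    Xf = np.where(np.isnan(x), 0.0, x)
    M = np.where(W, Y, 0.0)
    n = W.sum(axis=1).astype(float)
    Sx = W @ Xf
    Sxx = W @ (Xf * Xf)
    Sy = M.sum(axis=1)
    Sxy = M @ Xf
    Syy = (M * M).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = Sxx - Sx * Sx / n
        sxy_c = Sxy - Sx * Sy / n
        syy_c = Syy - Sy * Sy / n
        beta = sxy_c / sxx_c
        sse = np.maximum(syy_c - beta * sxy_c, 0.0)
        df = n - 2
        se = np.sqrt(sse / df / sxx_c)
        t = beta / se
    valid = (n >= 4) & (sxx_c > 0)
    p = np.full(len(beta), np.nan)
    good = valid & np.isfinite(t)
    p[good] = _t_pvalue(t[good], df[good])
    p[valid & np.isinf(t)] = _TINY_P
    for arr in (beta, se, t):
        arr[~valid] = np.nan
    return beta, se, t, p, n.astype(int)


def mirna_mrna_scan(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    fdr_alpha: float = 0.05,
    fdr_scope: str = "negative",
) -> pd.DataFrame:
    """Regress every mRNA on every miRNA over the shared samples.

    Complete cases per pair. q-values are BH-adjusted within the
    negative-slope partition by default (``fdr_scope="negative"``), matching
    an analysis that FDR-controls only the repression-direction tests;
    ``fdr_scope="all"`` adjusts family-wide instead. The significant set is
    negative-slope records with q < ``fdr_alpha``.
    """
    if fdr_scope not in ("negative", "all"):
        raise ValidationError("fdr_scope must be 'negative' or 'all'")
    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if not shared:
        raise ValidationError("no shared samples between miRNA and mRNA matrices")
    X = mirna.values[shared].to_numpy(dtype=float)
    Y = mrna.values[shared].to_numpy(dtype=float)
    frames = []
    for i, mir in enumerate(mirna.feature_ids):
        beta, se, t, p, n = _pairwise_simple_ols(X[i], Y)
        frames.append(pd.DataFrame({
            "x_id": mir, "y_id": mrna.feature_ids,
            "beta": beta, "se": se, "t": t, "p": p, "n": n,
        }))
    table = pd.concat(frames, ignore_index=True)
    dropped = int(table["p"].isna().sum())
    if dropped:
        logger.info("mirna_mrna_scan: %d pair(s) skipped (constant/too few obs)", dropped)
    table = table.dropna(subset=["p"]).reset_index(drop=True)
    table["q"] = np.nan
    if fdr_scope == "all":
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        neg = table["beta"] < 0
        if neg.any():
            table.loc[neg, "q"] = bh_fdr(table.loc[neg, "p"].to_numpy())
    n_sig = int(((table["beta"] < 0) & (table["q"] < fdr_alpha)).sum())
    logger.info("mirna_mrna_scan: %d tests, %d negative-slope records at q < %.3g",
                len(table), n_sig, fdr_alpha)
    return table


def significant_negative(table: pd.DataFrame, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Negative-slope records with q below ``fdr_alpha``."""
    return table[(table["beta"] < 0) & (table["q"] < fdr_alpha)].reset_index(drop=True)


def screen_covariates(
    y: np.ndarray, covariates: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Marginal per-covariate screen: include a covariate when the regression
    of the trait on it alone has p < ``alpha``."""
    selected = []
    for name in covariates.columns:
        rec = linear_assoc(covariates[name].to_numpy(float), y,
                           x_id=name, y_id="trait")
        if np.isfinite(rec["p"]) and rec["p"] < alpha:
            selected.append(name)
    return selected


def eqtl_scan(
    expr: ExpressionMatrix,
    g: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    covariate_screen_alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every (SNP, miRNA expression trait) pair by dosage regression.

    Assumes ``g`` already passed :func:`mireqtl.preprocess.filter_snps` and
    ``expr`` is already residualized if hidden-factor correction is wanted.
    Per trait, covariates are screened marginally, then every SNP is tested
    with the selected covariates; pairs use complete cases. The
    ``covariates_used`` column records the per-trait selection.
    """
    shared = [s for s in expr.sample_ids if s in set(g.sample_ids)]
    if not shared:
        raise ValidationError("no shared samples between expression and genotypes")
    if covariates is not None:
        missing = [s for s in shared if s not in covariates.index]
        if missing:
            raise ValidationError(f"covariates missing for samples {missing[:5]}")
        cov = covariates.loc[shared]
    else:
        cov = None
    E = expr.values[shared].to_numpy(dtype=float)
    D = g.dosage.loc[shared].to_numpy(dtype=float)
    snp_ids = np.asarray(g.snp_ids)
    frames = []
    for i, trait in enumerate(expr.feature_ids):
        y_full = E[i]
        obs = ~np.isnan(y_full)
        y = y_full[obs]
        selected: list[str] = []
        if cov is not None and cov.shape[1] > 0:
            selected = screen_covariates(y_full, cov, covariate_screen_alpha)
        Ci = cov[selected].to_numpy(float)[obs] if selected else np.empty((obs.sum(), 0))
        Di = D[obs]
        n = len(y)
        k = Ci.shape[1]
        p_model = 2 + k
        X0 = np.column_stack([np.ones(n), Ci])
        coef_y = np.linalg.lstsq(X0, y, rcond=None)[0]
        y_res = y - X0 @ coef_y

        complete = ~np.isnan(Di).any(axis=0)
        beta = np.full(len(snp_ids), np.nan)
        se = np.full(len(snp_ids), np.nan)
        tstat = np.full(len(snp_ids), np.nan)
        pval = np.full(len(snp_ids), np.nan)
        nvec = np.full(len(snp_ids), n, dtype=int)
        if complete.any() and n >= p_model + 1:
            Dc = Di[:, complete]
            D_res = Dc - X0 @ np.linalg.lstsq(X0, Dc, rcond=None)[0]
            sxx = (D_res * D_res).sum(axis=0)
            sxy = D_res.T @ y_res
            with np.errstate(invalid="ignore", divide="ignore"):
                b = sxy / sxx
                sse = np.maximum(y_res @ y_res - b * sxy, 0.0)
                df = n - p_model
                s = np.sqrt(sse / df / sxx)
                t = b / s
            valid = sxx > 1e-12 * (Dc * Dc).sum(axis=0)
            pv = np.full(len(b), np.nan)
            good = valid & np.isfinite(t)
            pv[good] = _t_pvalue(t[good], np.full(good.sum(), df))
            pv[valid & np.isinf(t)] = _TINY_P
            b[~valid] = s[~valid] = t[~valid] = np.nan
            idx = np.where(complete)[0]
            beta[idx], se[idx], tstat[idx], pval[idx] = b, s, t, pv
        # SNPs with missing dosage calls: per-pair complete-case OLS
        for j in np.where(~complete)[0]:
            rec = linear_assoc(Di[:, j], y, covariates=Ci if k else None,
                               x_id=str(snp_ids[j]), y_id=trait)
            beta[j], se[j], tstat[j] = rec["beta"], rec["se"], rec["t"]
            pval[j], nvec[j] = rec["p"], rec["n"]
        frames.append(pd.DataFrame({
            "x_id": snp_ids, "y_id": trait, "beta": beta, "se": se, "t": tstat,
            "p": pval, "n": nvec, "q": np.nan,
            "covariates_used": ",".join(selected),
        }))
    table = pd.concat(frames, ignore_index=True)
    n_skip = int(table["p"].isna().sum())
    if n_skip:
        logger.info("eqtl_scan: %d pair(s) skipped", n_skip)
    return table.dropna(subset=["p"]).reset_index(drop=True)


def bonferroni_threshold(alpha: float = 0.05, n_snps: int = 1, n_traits: int = 1) -> float:
    """Family-wise threshold alpha / (n_snps * n_traits)."""
    if n_snps < 1 or n_traits < 1:
        raise ValidationError("n_snps and n_traits must be >= 1")
    return alpha / (n_snps * n_traits)


@dataclass
class EffectSizeSummary:
    mean: float
    sd: float
    n: int


def effect_size_summary(
    records: pd.DataFrame, q_max: float = 0.05, sign: str = "negative"
) -> EffectSizeSummary:
    """Mean and SD of slopes over records with q < ``q_max`` and the given
    sign restriction (``"negative"`` or ``"all"``)."""
    if sign not in ("negative", "all"):
        raise ValidationError("sign must be 'negative' or 'all'")
    sel = records[records["q"] < q_max]
    if sign == "negative":
        sel = sel[sel["beta"] < 0]
    betas = sel["beta"].to_numpy(dtype=float)
    if len(betas) == 0:
        return EffectSizeSummary(np.nan, np.nan, 0)
    sd = float(np.std(betas, ddof=1)) if len(betas) > 1 else 0.0
    return EffectSizeSummary(float(betas.mean()), sd, len(betas))
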