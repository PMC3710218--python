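"""Resampling-based enrichment inference.

The common engine is the allele-frequency-matched null set: given a query set
of SNPs, draw B random SNP sets from the genotyping pool with, bin by bin,
exactly the query's minor-allele-frequency profile. Any overlap statistic
computed on the query is then referred to its empirical null distribution
over the B matched sets; the empirical p-value is the fraction of null sets
whose statistic matches or exceeds the observed one.

On top of this sit:

* ``overlap_enrichment`` — count of query SNPs inside a target set.
* ``multi_target_enrichment`` — count of query SNPs associated with at least
  two distinct traits (miRNAs) at a p threshold.
* ``geneset_regulation_test`` — a gene-set permutation test: the median of
  per-gene best negative-association p-values for a focal gene set against
  medians of random same-size gene sets.
* ``qq_curve``, ``tail_proportion_test``, ``group_effectsize_test``,
  ``sign_balance_test`` — the surrounding descriptive comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NullSetCollection:
    """B resampled SNP-id sets matched to the query's per-bin MAF profile."""

    query_ids: list[str]
    bin_edges: np.ndarray
    bin_profile: np.ndarray  # per-bin query counts
    sets: list[np.ndarray]  # B arrays of SNP ids
    seed: int | None

    @property
    def B(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """Observed statistic against its matched-resampling null."""

    observed: float
    null_values: np.ndarray
    B: int

    @property
    def empirical_p(self) -> float:
        """Fraction of null statistics that match or exceed the observed."""
        return float(np.sum(self.null_values >= self.observed) / self.B)

    @property
    def p_label(self) -> str:
        """Human-readable p; '< 1/B' when no null value qualifies."""
        if np.sum(self.null_values >= self.observed) == 0:
            return f"< {1.0 / self.B:g}"
        return f"{self.empirical_p:g}"


def _maf_bins(maf: np.ndarray, bin_width: float) -> np.ndarray:
    """Assign MAF values in [0, 0.5] to bins of width ``bin_width``; the
    right edge 0.5 falls into the last bin."""
    n_bins = int(np.ceil(0.5 / bin_width))
    idx = np.floor(maf / bin_width).astype(int)
    return np.minimum(idx, n_bins - 1)


def maf_matched_null_sets(
    query,
    pool: pd.DataFrame,
    B: int = 1000,
    bin_width: float = 0.05,
    seed: int | None = None,
    exclude_query: bool = True,
) -> NullSetCollection:
    """Draw B SNP sets matching the query's per-bin MAF counts.

    ``pool`` is a frame with a ``maf`` column indexed by snp_id (the
    ``snps`` table of a :class:`~mireqtl.core.GenotypeMatrix`). Sampling is
    without replacement within each set and independent across sets; query
    SNPs are excluded from the candidate pool unless ``exclude_query`` is
    False. Raises when a bin occupied by the query has fewer candidates than
    the query count for that bin.
    """
    query = list(dict.fromkeys(query))
    maf = pool["maf"]
    missing = [s for s in query if s not in maf.index or not np.isfinite(maf[s])]
    if missing:
        raise ValidationError(f"query SNPs absent from pool or lacking maf: {missing[:5]}")
    n_bins = int(np.ceil(0.5 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    pool_ids = maf.index.to_numpy()
    pool_bins = _maf_bins(maf.to_numpy(dtype=float), bin_width)
    query_bins = _maf_bins(maf.loc[query].to_numpy(dtype=float), bin_width)
    profile = np.bincount(query_bins, minlength=n_bins)

    rng = np.random.default_rng(seed)
    in_query = np.isin(pool_ids, query)
    sets_parts: list[list[np.ndarray]] = [[] for _ in range(B)]
    for b in np.nonzero(profile)[0]:
        need = int(profile[b])
        cand_mask = pool_bins == b
        if exclude_query:
            cand_mask &= ~in_query
        cand = pool_ids[cand_mask]
        if len(cand) < need:
            raise ValidationError(
                f"MAF bin [{edges[b]:.3g}, {edges[b + 1]:.3g}) has only "
                f"{len(cand)} candidate SNPs but the query needs {need}; "
                "consider a larger bin_width"
            )
        # one argpartition per set-batch: random keys, take the `need` smallest
        keys = rng.random((B, len(cand)))
        take = np.argpartition(keys, need - 1, axis=1)[:, :need]
        for i in range(B):
            sets_parts[i].append(cand[take[i]])
    sets = [np.concatenate(parts) if parts else np.empty(0, dtype=pool_ids.dtype)
            for parts in sets_parts]
    return NullSetCollection(query, edges, profile, sets, seed)


def overlap_enrichment(query, target, nulls: NullSetCollection) -> EnrichmentResult:
    """Observed |query ∩ target| against per-null-set overlap counts."""
    target = set(target)
    observed = len(set(query) & target)
    null_values = np.array([sum(x in target for x in s.tolist())
                            for s in nulls.sets], dtype=float)
    return EnrichmentResult(float(observed), null_values, nulls.B)


def _multi_target_counts(assoc: pd.DataFrame, p_max: float) -> pd.Series:
    hits = assoc[assoc["p"] < p_max]
    return hits.groupby("x_id")["y_id"].nunique()


def multi_target_enrichment(
    query,
    assoc: pd.DataFrame,
    p_max: float,
    nulls: NullSetCollection,
    statistic: str = "count_ge2",
) -> EnrichmentResult:
    """Are query SNPs more often associated with multiple traits than matched SNPs?

    The default statistic for a SNP set is the number of its SNPs associated
    (p < ``p_max``) with >= 2 distinct y features; ``statistic="mean_targets"``
    uses the mean per-SNP count of associated features instead.
    """
    if statistic not in ("count_ge2", "mean_targets"):
        raise ValidationError("statistic must be 'count_ge2' or 'mean_targets'")
    counts = _multi_target_counts(assoc, p_max).to_dict()

    def stat(ids) -> float:
        c = np.array([counts.get(x, 0) for x in ids], dtype=float)
        return float((c >= 2).sum()) if statistic == "count_ge2" else float(c.mean())

    observed = stat(query)
    null_values = np.array([stat(s) for s in nulls.sets])
    return EnrichmentResult(observed, null_values, nulls.B)


@dataclass
class GeneSetTestResult:
    """Gene-set regulation permutation test output."""

    focal_best_p: pd.Series  # best negative-association p per focal gene
    observed_median: float
    null_medians: np.ndarray
    B: int
    qq_pairs: pd.DataFrame = field(repr=False)
    n_excluded: int = 0
    exhaustive: bool = False

    @property
    def empirical_p(self) -> float:
        """Fraction of null medians at or below the observed (smaller median
        = stronger regulation)."""
        return float(np.sum(self.null_medians <= self.observed_median) / self.B)

    @property
    def p_label(self) -> str:
        if np.sum(self.null_medians <= self.observed_median) == 0:
            return f"< {1.0 / self.B:g}"
        return f"{self.empirical_p:g}"


def best_p_per_gene(assoc: pd.DataFrame) -> pd.Series:
    """Smallest negative-slope association p-value per target gene (y_id)."""
    neg = assoc[assoc["beta"] < 0]
    return neg.groupby("y_id")["p"].min()


def geneset_regulation_test(
    assoc: pd.DataFrame,
    focal_genes,
    universe,
    B: int = 1000,
    seed: int | None = None,
    exclude_focal: bool = True,
    statistic: str = "best_p_median",
    max_enumeration: int = 10_000,
) -> GeneSetTestResult:
    """Is the focal gene set under stronger negative miRNA regulation than
    random same-size gene sets?

    Each universe gene is summarized by its best (smallest) negative-slope
    association p over all miRNAs (``statistic="best_p_median"``; the
    ``"all_pairs_median"`` alternative uses the median over all of a set's
    negative-slope pair p-values). The observed statistic is the median over
    focal genes; the null is the same statistic on B random same-size subsets
    of the universe (focal genes excluded from the null pool when
    ``exclude_focal``). When the number of possible subsets is at most
    ``max_enumeration``, all of them are enumerated instead of sampled.
    Genes with no tested negative association are excluded and counted.
    """
    if statistic not in ("best_p_median", "all_pairs_median"):
        raise ValidationError("statistic must be 'best_p_median' or 'all_pairs_median'")
    focal = list(dict.fromkeys(focal_genes))
    universe = list(dict.fromkeys(universe))
    if not set(focal) <= set(universe):
        raise ValidationError("focal genes must be a subset of the universe")
    if len(focal) > len(universe):
        raise ValidationError("focal set larger than universe")

    neg = assoc[assoc["beta"] < 0]
    best = neg.groupby("y_id")["p"].min()
    tested = set(best.index)
    focal_kept = [g for g in focal if g in tested]
    n_excluded = len(focal) - len(focal_kept)
    if n_excluded:
        logger.info("geneset_regulation_test: %d focal gene(s) with no tested "
                    "negative association excluded", n_excluded)
    if not focal_kept:
        raise ValidationError("no focal gene has a tested negative association")
    universe_kept = [g for g in universe if g in tested]
    size = len(focal_kept)

    if statistic == "best_p_median":
        def set_stat(genes) -> float:
            return float(np.median(best.loc[list(genes)].to_numpy()))
        focal_vals = best.loc[focal_kept]
    else:
        by_gene = {g: grp["p"].to_numpy() for g, grp in neg.groupby("y_id")}

        def set_stat(genes) -> float:
            return float(np.median(np.concatenate([by_gene[g] for g in genes])))
        focal_vals = best.loc[focal_kept]  # per-gene best p still reported

    observed = set_stat(focal_kept)
    pool = [g for g in universe_kept if g not in set(focal_kept)] if exclude_focal \
        else universe_kept
    if len(pool) < size:
        raise ValidationError("null pool smaller than the focal set")

    n_subsets = math.comb(len(pool), size)
    exhaustive = n_subsets <= max_enumeration
    null_sets: list[list[str]]
    if exhaustive:
        null_sets = [list(c) for c in combinations(pool, size)]
    else:
        rng = np.random.default_rng(seed)
        pool_arr = np.asarray(pool)
        null_sets = [list(rng.choice(pool_arr, size=size, replace=False))
                     for _ in range(B)]
    null_medians = np.array([set_stat(s) for s in null_sets])

    # expected QQ curve: mean of sorted per-gene best-p vectors across draws
    sorted_nulls = np.sort(np.array([best.loc[s].to_numpy() for s in null_sets]), axis=1)
    expected = sorted_nulls.mean(axis=0)
    obs_sorted = np.sort(focal_vals.to_numpy())
    qq = pd.DataFrame({
        "expected_neglog10_p": -np.log10(expected),
        "observed_neglog10_p": -np.log10(np.maximum(obs_sorted, np.nextafter(0, 1))),
    })
    return GeneSetTestResult(
        focal_best_p=focal_vals,
        observed_median=observed,
        null_medians=null_medians,
        B=len(null_sets),
        qq_pairs=qq,
        n_excluded=n_excluded,
        exhaustive=exhaustive,
    )


def qq_curve(observed_p, expected="uniform") -> pd.DataFrame:
    """Paired observed/expected quantiles on the -log10 scale.

    ``expected`` is either ``"uniform"`` (expected quantiles (i - 0.5) / m)
    or a 2-D array of null p-value vectors whose sorted rows are averaged
    into a mean order-statistic curve (interpolated to m points when the
    null vectors have a different length).
    """
    p = np.asarray(observed_p, dtype=float)
    if len(p) == 0:
        raise ValidationError("observed p-values must be non-empty")
    if (p == 0).any():
        logger.warning("qq_curve: %d zero p-value(s) clamped", int((p == 0).sum()))
        p = np.maximum(p, np.nextafter(0, 1))
    m = len(p)
    obs = np.sort(p)
    if isinstance(expected, str):
        if expected != "uniform":
            raise ValidationError("expected must be 'uniform' or an array of null vectors")
        exp = (np.arange(1, m + 1) - 0.5) / m
    else:
        null = np.asarray(expected, dtype=float)
        if null.ndim != 2:
            raise ValidationError("null vectors must be a 2-D array (B x m)")
        curve = np.sort(null, axis=1).mean(axis=0)
        if len(curve) == m:
            exp = curve
        else:
            grid = (np.arange(1, m + 1) - 0.5) / m
            src = (np.arange(1, len(curve) + 1) - 0.5) / len(curve)
            exp = np.interp(grid, src, curve)
    return pd.DataFrame({
        "expected_neglog10_p": -np.log10(exp),
        "observed_neglog10_p": -np.log10(obs),
    })


def tail_proportion_test(
    focal_betas, beta_cut: float = -4.0, background_prop: float = 0.05
) -> tuple[float, float]:
    """Proportion of genes with slope below ``beta_cut`` against a genome-wide
    background rate, one-sided exact binomial."""
    betas = np.asarray(focal_betas, dtype=float)
    if len(betas) == 0:
        raise ValidationError("focal_betas must be non-empty")
    k = int(np.sum(betas < beta_cut))
    n = len(betas)
    res = stats.binomtest(k, n, background_prop, alternative="greater")
    return k / n, float(res.pvalue)


def group_effectsize_test(assoc: pd.DataFrame, member_mirnas) -> tuple[float, float]:
    """Welch one-sided t-test: |slope| of records from member miRNAs vs the rest.

    Alternative: the member group has larger absolute effect sizes. Returns
    (t, p); (nan, nan) with a log entry when either group has < 2 records.
    """
    members = set(member_mirnas)
    in_group = assoc["x_id"].isin(members)
    a = assoc.loc[in_group, "beta"].abs().to_numpy()
    b = assoc.loc[~in_group, "beta"].abs().to_numpy()
    if len(a) < 2 or len(b) < 2:
        logger.warning("group_effectsize_test: a group has < 2 records "
                       "(%d vs %d); undefined", len(a), len(b))
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(t), float(p)


def sign_balance_test(directions) -> float:
    """Two-sided exact binomial test of positive vs negative effect
    directions (zeros excluded); detects a systematic risk-allele direction."""
    d = np.asarray(directions, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValidationError("no nonzero directions supplied")
    k = int(np.sum(d > 0))
    return float(stats.binomtest(k, len(d), 0.5, alternative="two-sided").pvalue)
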