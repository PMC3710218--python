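# Methods

This note documents the statistical procedures implemented in `mireqtl`,
the defaults and their rationale, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model

All matrices are pandas-backed. Genotypes are hard-call alt-allele dosages
in {0, 1, 2} with `NaN` for missing; positions are 1-based (VCF convention);
only biallelic variants are supported (multi-allelic VCF records are skipped
with a warning). Expression matrices are feature × sample on the log2 scale
with `NaN` missing values; the only textual missing markers accepted in TSV
input are `NA` and the empty cell. Fractional imputed dosages read from a
VCF `DS` field are rounded to the nearest hard call (`dosage_mode="ds"`):
hard calls keep the Hardy–Weinberg genotype counts well defined, and every
downstream formula is a dosage regression for which rounding changes little
at the MAFs retained by the filters.

## Preprocessing

**Expressed call.** A feature is *expressed* when at least 75% of samples
have a non-missing value (`min_frac=0.75`, boundary inclusive). This mirrors
array practice where failed probes produce missing calls; features failing
the call are dropped before any scan.

**Scales.** miRNA phenotypes are used on the log2 scale as supplied (the
`log2_transform` helper exists for raw intensities). mRNA matrices are
quantile-normalized: every sample's order statistics are replaced by the
across-sample mean order statistic, ties receiving the average of the
reference values over the tied ranks. The transform is idempotent and
requires a complete matrix. Whether to quantile-normalize the miRNA matrix
as well is left to the caller; the pipeline default is log2 only, because
miRNA panels are small enough that forcing a common distribution can distort
genuinely shifted features.

**SNP filters.** MAF strictly greater than 0.15 (the boundary value 0.15 is
*excluded*) and Hardy–Weinberg exact-test p ≥ 10⁻³. The HWE test is the
Levene–Haldane conditional distribution: given the minor-allele count, the
probability of each heterozygote count is proportional to
C(n, h)·C(n−h, n_hom_rare)·2ʰ; the two-sided p sums the probabilities of all
heterozygote counts whose probability does not exceed the observed one. The
implementation uses exact integer weights (no floating-point rounding can
change which terms are included); monomorphic SNPs return p = 1 by
convention. Heterozygote-*deficit* departures — the signature of genotyping
artifacts — are what this filter removes.

**Genotype PCs.** Ancestry covariates are the top-k (default 3) principal
components of the sample × SNP matrix after per-SNP centering and
unit-variance scaling; missing dosages are mean-imputed for this computation
only. The component sign is fixed by making each component's
largest-magnitude SNP loading positive, so reruns are bit-identical.

**Hidden-factor removal.** Latent expression factors (batch, technical,
physiological) are estimated as the top-k principal components of the
feature-centered expression matrix — a deterministic PCA stand-in for
probabilistic factor frameworks, with k = 4 by default following the
diagnostic choice used in liver miRNA data. Missing values are mean-imputed,
and supplied covariates regressed out, *for the estimation step only*; each
feature is then regressed on the factor scores over its complete cases and
replaced by the residuals. Residuals are exactly orthogonal to the factor
scores on each feature's observed samples. The per-feature correlation
between pre- and post-adjustment values is reported: in weak-factor regimes
it stays high (median > 0.8), meaning the adjustment is nearly inert when no
structure exists to remove.

## Association scans

A single OLS engine underlies both scans; p-values are two-sided from the t
distribution with n − p_model degrees of freedom, where n is the
complete-case count and p_model the number of regression parameters. Missing
data are handled by pairwise deletion (complete cases per pair), never by
imputation. A constant predictor, or n < p_model + 1, yields a skipped
record (logged). Exact-zero p-values are clamped to the smallest positive
double.

**miRNA–mRNA scan.** One regression of mRNA on miRNA per pair, vectorized
over mRNAs with pairwise-complete sufficient statistics. Records are
partitioned by slope sign; Benjamini–Hochberg q-values are computed within
the negative-slope partition (the repression direction is the hypothesis
family of interest), with a `fdr_scope="all"` flag for family-wide
adjustment as a sensitivity analysis. Directionality is imposed by sign
filtering of two-sided tests, not by one-sided testing, so both scans share
one engine. Under the null, sign and |t| are independent, so the partition
does not distort the FDR guarantee.

**eQTL scan.** Per trait: each candidate covariate is screened marginally
(trait regressed on that covariate alone) and included when p < 0.05 — the
minimal reading of conditional covariate use; the screen α is configurable.
The selected covariates are projected out of the phenotype and of every
complete SNP column (Frisch–Waugh–Lovell), giving slopes, SEs and p-values
identical to the full multiple regression at scan speed; SNPs with missing
calls fall back to per-pair complete-case OLS. With no covariates the scan
reproduces pairwise simple regression to floating-point identity.

**Significance tiers.** The family-wise (Bonferroni) threshold is
α / (n_SNPs × n_traits); a fixed suggestive tier (default 10⁻⁸) is also
reported. The effect-size summary (mean, SD, n of significant negative
slopes) describes the genome-wide background against which specific gene
sets are compared.

## Resampling enrichment

**MAF-matched null sets.** The MAF axis [0, 0.5] is cut into bins of width
0.05 (configurable; 0.05 balances matching fidelity against bin starvation —
a bin the query occupies must contain at least the query's count of
candidate SNPs, and the error message suggests widening the bins when it
does not). Each of B null sets draws, without replacement within the set,
the query's per-bin counts from the pool; query SNPs themselves are excluded
from the candidate pool by default (a flag restores them), preventing
trivial self-overlap inflation. Matching is exact by construction and
asserted in tests.

**Empirical p.** #{null ≥ observed}/B, with ties counting toward the
numerator ("matches or exceeds"); a zero count is reported as "< 1/B". No
pseudocount is added by default (a flag-free property of the estimator the
tests calibrate); because overlap counts are small integers, the estimator
is slightly conservative under the null, which the calibration tests
account for.

**Multi-target statistic.** The default statistic is the number of query
SNPs associated with ≥ 2 distinct miRNAs at the chosen p threshold — the
minimal operationalization of "regulates multiple miRNAs" — with a
mean-target-count alternative behind a flag.

**Gene-set regulation test.** Each universe gene maps to its best (smallest)
negative-association p over all miRNAs (genes with no tested negative
association are excluded and counted); the observed statistic is the focal
set's median, the null the medians of B random same-size sets drawn from the
universe excluding the focal genes (an `exclude_focal=False` flag includes
them; an `all_pairs_median` flag replaces the per-gene best-p summary with
the median over all of a set's pair p-values). When the number of possible
subsets is ≤ 10⁴ the test enumerates all of them instead of sampling, which
is exact. The QQ diagnostic pairs the sorted focal best-p values against the
mean of the sorted null vectors, on the −log10 scale.

**Surrounding comparisons.** The tail-proportion test is a one-sided exact
binomial on the fraction of focal genes whose best slope is below a cut
(default −4) against a genome-wide background rate (default 5%). The group
effect-size comparison is a Welch (unequal-variance) one-sided t-test on
|slope| — member-group larger — avoiding an equal-variance assumption the
data give no reason to make. Risk-allele direction balance is a two-sided
exact binomial test of positive vs negative directions with zeros excluded.

**QQ curves.** Observed p-values sorted ascending against expected
quantiles (i − 0.5)/m in uniform mode, or against the mean order-statistic
curve of supplied null vectors (interpolated when lengths differ); output on
the −log10 scale, with zero p-values clamped and a warning.

## Annotation

eQTL records below a join threshold (default 10⁻⁴, a deliberately liberal
tier for annotating SNPs that carry prior evidence) are inner-joined with
catalog rows by SNP. The direction of effect per risk-allele copy is
sign(β_alt) when the risk allele is the alt allele and −sign(β_alt) when it
is the ref allele — the standard orientation convention, documented as an
assumption; a risk allele matching neither allele leaves the direction
absent. The pharmacogenetic screen treats the catalog's SNPs as the query,
SNPs with any miRNA association at p < 10⁻³ as the target, and delegates to
the overlap enrichment; evidence levels {1, 2, 3} are carried as opaque
metadata with an optional {1, 2} restriction.

## Synthetic cohorts

The generator's defaults emulate the cohort structure the pipeline targets:
79 samples; 277 expressed miRNAs plus 573 probed-but-unexpressed features
whose 60% missingness rate fails the expressed call; a 2,000-gene mRNA panel
(a scaled-down transcriptome — full-size panels are supported but slower);
5,000 biallelic SNPs with MAF uniform on (0.05, 0.5); 4 hidden factors
(scores N(0, factor_sd²), loadings N(0, 1)); Gaussian noise (sd 1);
missingness completely at random at 5% on expressed features; regulation
slopes from Normal(−1.21, 1.05²) truncated to strictly negative values, the
documented effect-size distribution for significant negative miRNA–mRNA
associations; eQTL slopes from Normal(1, 0.25²), a size detectable but not
trivial at n ≈ 79–200. HWE violators are generated by multiplying the
heterozygote probability by 0.1 and renormalizing — the simplest
one-parameter departure, in the direction genotyping errors push. Planted
eQTLs are assigned to miRNAs without positional constraint (the scan treats
all SNP–trait pairs as one family, so cis/trans geography is irrelevant to
every statistic computed here). Catalogs contain a controlled fraction of
planted eQTL SNPs, which carry the alt allele as risk allele.

Each of the four generators derives an independent random stream from the
config seed, so any subset of outputs is reproducible bit-for-bit.

What the generator does **not** emulate — and therefore what passing
recovery tests do not establish about real data: linkage disequilibrium
between SNPs (matching on MAF alone is exactly what the enrichment tests
assume, but real catalogs carry LD structure); informative missingness
(real array missingness is intensity-dependent, not MCAR); population
structure beyond an optional two-subpopulation frequency shift used to test
PC correction; probe-level measurement error and normalization artifacts;
and correlated regulatory networks (planted effects are independent).

## Problem sizes and determinism

The test suite and acceptance script run simulations at desk scale, chosen
as the smallest sizes at which the asserted properties are statistically
stable: scans of 2,000 SNPs × 50 traits at n = 200 over 50 seeds for eQTL
recovery; 100 × 500 all-null pair scans over 50 seeds for FDR control;
B = 200–1,000 resampled sets with pools of 3,000–5,000 SNPs for the
enrichment calibrations; and the full 150-miRNA × 2,000-gene design for the
gene-set target. All randomness flows through explicit seeds; reruns are
byte-identical (asserted for the end-to-end pipeline).

## Known limitations

* PCA factor removal approximates probabilistic factor models; when factor
  and genetic effects are correlated it can absorb part of a true signal.
* Covariate screening at marginal p < 0.05 is a heuristic; it can omit
  confounders that act jointly but not marginally.
* The BH guarantee within the negative partition assumes the usual
  positive-dependence conditions; heavy inter-gene correlation can make the
  realized FDP noisier than the nominal level.
* Empirical p-values are bounded below by 1/B; claims beyond that resolution
  require more null sets.
* No LD-aware matching or clumping: enrichment p-values are valid under the
  matched-MAF null, which ignores correlation between neighboring SNPs.
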