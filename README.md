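# mireqtl

Integrative miRNA analysis for genotyped expression cohorts: miRNA–mRNA
negative-association scanning, miRNA expression QTL (miR-eQTL) mapping, and a
family of allele-frequency-matched resampling enrichment tests, with a
synthetic cohort generator that records its full ground truth.

## Who this is for

Statistical geneticists and regulatory genomicists who have, for one cohort,
(i) genotype dosages, (ii) a miRNA expression matrix, and optionally (iii) an
mRNA expression matrix and annotation catalogs (trait-associated SNPs,
pharmacogenetic variants), and who want to ask:

* which miRNAs repress which transcripts (negative regression slope, FDR
  controlled);
* which SNPs act as miR-eQTLs (dosage regression per SNP–miRNA pair, with
  MAF/HWE filters, screened covariates, hidden-factor correction, and
  Bonferroni/suggestive significance tiers);
* whether a SNP set (e.g. an annotation catalog, or the miR-eQTLs themselves)
  is *enriched* in another SNP set beyond what allele-frequency-matched random
  SNP sets achieve;
* whether a designated gene set (e.g. key pharmacogenes) is under stronger
  miRNA regulation than random same-size gene sets.

## The models

**Association scans.** Every test is an ordinary least-squares regression.
For a miRNA–mRNA pair, mRNA expression *y* is regressed on miRNA expression
*x*: *y = α + βx + ε*; repression corresponds to *β* < 0, and
Benjamini–Hochberg q-values are computed within the negative-slope partition.
For an eQTL, miRNA expression is regressed on alt-allele dosage
*g* ∈ {0, 1, 2}: *y = α + βg + γᵀc + ε*, where the covariates *c* (age, sex,
genotype PCs) are included per trait only when marginally associated
(p < 0.05). SNPs are pre-filtered to MAF > 15% and Hardy–Weinberg
exact-test p ≥ 10⁻³ (Levene–Haldane conditional distribution, exact integer
arithmetic). Hidden expression factors are estimated as the top-k principal
components of the phenotype matrix (k = 4 by default) and regressed out of
every feature before the scan.

**Matched-resampling enrichment.** For a query SNP set *Q* and statistic
*T* (overlap with a target set; count of SNPs regulating ≥ 2 miRNAs), B
random sets with exactly *Q*'s per-bin MAF profile (bins of width 0.05 on
[0, 0.5]) give the empirical null, and

&nbsp;&nbsp;&nbsp;&nbsp;empirical p = #{b : T(null_b) ≥ T(Q)} / B,

reported as "< 1/B" when no null set qualifies. The gene-set regulation test
is the same idea over genes: each gene is summarized by its best (smallest)
negative-association p-value, the observed statistic is the focal set's
median, and the null is the median over random same-size gene sets (with
exhaustive enumeration replacing sampling on small universes).

**Synthetic cohorts.** The generator draws genotypes from Hardy–Weinberg
proportions over a configurable MAF spectrum (optionally with
heterozygote-deficit violators), builds miRNA expression from planted
trans-eQTL effects + hidden factors + noise, builds mRNA expression from
planted strictly negative regulation effects (default slope distribution
Normal(−1.21, 1.05²) truncated to negatives), and emits an annotation catalog
with a controlled overlap with the planted eQTL SNPs. Every planted effect is
recorded in a `TruthSet`.

## Worked example

```python
import numpy as np
from mireqtl import (SimulationConfig, bonferroni_threshold, call_expressed,
                     eqtl_scan, filter_snps, genotype_pcs,
                     remove_hidden_factors, simulate_cohort)

cfg = SimulationConfig(
    n_samples=120, n_snps=1500, n_mirnas=40, n_low_quality_mirnas=10,
    n_mrnas=50, n_planted_eqtls=5, n_planted_regulations=0,
    eqtl_beta_sampler=lambda rng, k: np.full(k, 1.2),
    n_hidden_factors=4, factor_sd=1.2, maf_low=0.1, catalog_size=0, seed=7)
cohort = simulate_cohort(cfg)

mirna = call_expressed(cohort.mirna, min_frac=0.75)
g = filter_snps(cohort.genotypes, maf_min=0.15, hwe_alpha=0.001)
resid, adj = remove_hidden_factors(mirna, k=4)
eqtls = eqtl_scan(resid, g, covariates=genotype_pcs(g, k=3))
thr = bonferroni_threshold(0.05, g.n_snps, mirna.n_features)
print(eqtls[eqtls.p < thr].sort_values("p")[["x_id", "y_id", "beta", "p"]])
```

prints (see `examples/02_eqtl_scan.py` for the full script):

```
  x_id   y_id     beta            p
rs1302 miR-22 1.282474 1.163644e-17
rs1153  miR-7 1.174918 6.421150e-16
 rs168 miR-29 1.000601 3.431517e-11
 rs389 miR-24 0.901891 9.122933e-11
```

Four of the five planted eQTLs (true slope 1.2 per alt-allele copy) exceed
the Bonferroni threshold 9.6 × 10⁻⁷; the estimated slopes are per alt-allele
copy on the log2-expression scale, and the fifth effect falls in the
suggestive tier. The `examples/` directory holds one short narrative script
per capability: cohort simulation, the eQTL scan, the miRNA–mRNA pair scan
with effect-size summaries, and the enrichment battery.

A thin CLI wraps the same functions
(`mireqtl simulate|preprocess|scan-pairs|scan-eqtl|enrich-overlap|enrich-multi|geneset-test|qq|annotate|run`);
`mireqtl run --config cfg.yaml` executes the whole pipeline from a flat YAML
config and writes every intermediate TSV plus a JSON summary.

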