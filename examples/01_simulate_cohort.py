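"""Generate a synthetic liver-style cohort and inspect its ground truth.

The generator plants trans-eQTL effects on miRNAs, negative miRNA->mRNA
regulation, hidden expression factors, and an annotation catalog that
partially overlaps the planted eQTL SNPs. Everything is reproducible from
the config seed.
"""

from mireqtl import SimulationConfig, simulate_cohort

cfg = SimulationConfig(
    n_samples=79,          # cohort size
    n_snps=2000,           # genotyped SNPs (scaled down)
    n_mirnas=60,           # expressed miRNAs
    n_low_quality_mirnas=20,  # probed features that will fail the expressed call
    n_mrnas=300,           # mRNA transcripts (scaled down)
    n_planted_eqtls=8,     # SNPs with a true effect on a miRNA
    n_planted_regulations=20,  # true negative miRNA->mRNA pairs
    n_hidden_factors=4,    # latent technical/physiological factors
    catalog_size=50,
    catalog_fraction_overlapping=0.16,
    seed=42,
)
cohort = simulate_cohort(cfg)

print(f"genotypes: {cohort.genotypes.n_samples} samples x "
      f"{cohort.genotypes.n_snps} SNPs")
print(f"miRNA matrix: {cohort.mirna.n_features} features "
      f"({cfg.n_mirnas} expressed + {cfg.n_low_quality_mirnas} low-quality)")
print(f"mRNA matrix: {cohort.mrna.n_features} features")
print("\nplanted eQTLs (SNP -> miRNA, slope per alt-allele copy):")
print(cohort.truth.planted_eqtls.head())
print("\nplanted regulations (miRNA -> mRNA, all slopes negative):")
print(cohort.truth.planted_regulations.head())
print(f"\ncatalog entries overlapping planted eQTL SNPs: "
      f"{cohort.catalog['snp_id'].isin(cohort.truth.planted_eqtls['snp_id']).sum()}"
      f" of {len(cohort.catalog)}")
# The truth tables are what recovery tests compare scan output against.
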