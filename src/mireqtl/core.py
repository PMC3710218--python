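"""Core domain containers for the miR-eQTL pipeline.

Genotypes, expression matrices, covariates, and annotation catalogs are thin
dataclass wrappers around :class:`pandas.DataFrame`, with the orientation and
value conventions every downstream stage relies on:

* **GenotypeMatrix** — sample x SNP allele-dosage values in {0, 1, 2} with
  ``NaN`` for missing calls, plus per-SNP metadata (chromosome, 1-based
  position, ref/alt alleles, minor allele frequency, HWE exact-test p-value).
* **ExpressionMatrix** — feature x sample log2-scale values (miRNA or mRNA),
  ``NaN`` allowed.
* **CovariateTable** — sample x covariate table (age, sex, genotype PCs);
  no missing values.
* **CatalogTable** — trait- or drug-associated SNP annotations with an
  optional risk allele and an optional evidence level in {1, 2, 3}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIRNA = "miRNA"
MRNA = "mRNA"

#: Column order of the per-SNP metadata table.
SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "maf", "hwe_p"]

#: Column order of association-result tables.
ASSOC_COLUMNS = ["x_id", "y_id", "beta", "se", "t", "p", "n", "q"]

#: Column order of catalog tables.
CATALOG_COLUMNS = ["snp_id", "annotation", "risk_allele", "evidence_level", "source"]


class ValidationError(ValueError):
    """Input violates a documented contract (bad shape, value, or config)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


def _require_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class GenotypeMatrix:
    """Hard-call allele dosages with per-SNP metadata.

    Parameters
    ----------
    dosage:
        sample x SNP frame; values in {0, 1, 2} (alt-allele copies) or NaN.
    snps:
        per-SNP metadata indexed by ``snp_id`` (see :data:`SNP_COLUMNS`).
    """

    dosage: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.dosage.columns, "snp_id")
        _require_unique(self.dosage.index, "sample_id")
        if "snp_id" in self.snps.columns:
            self.snps = self.snps.set_index("snp_id")
        if not self.snps.index.equals(pd.Index(self.dosage.columns)):
            if set(self.snps.index) != set(self.dosage.columns):
                raise ValidationError("snps metadata does not match dosage columns")
            self.snps = self.snps.loc[self.dosage.columns]
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"dosage value {vals[tuple(bad)]!r} at sample "
                f"{self.dosage.index[bad[0]]!r}, snp {self.dosage.columns[bad[1]]!r} "
                "not in {0, 1, 2, missing}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(self.dosage[snp_ids], self.snps.loc[snp_ids].copy())

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[list(sample_ids)], self.snps.copy())


def compute_maf(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill the ``maf`` column of ``g.snps`` from the dosage matrix.

    The alt-allele frequency is ``sum(dosage) / (2 * n_nonmissing)`` and the
    minor allele frequency is ``min(f, 1 - f)``, invariant under ref/alt
    relabeling. SNPs with no non-missing call get ``maf = NaN`` and are
    flagged for downstream exclusion.
    """
    vals = g.dosage.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(vals, axis=0) / (2.0 * n_obs)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf[n_obs == 0] = np.nan
    if (n_obs == 0).any():
        bad = list(np.asarray(g.snp_ids)[n_obs == 0][:5])
        logger.warning("%d SNP(s) with all calls missing (e.g. %s); maf undefined",
                       int((n_obs == 0).sum()), bad)
    g.snps["maf"] = maf
    return g


def genotype_counts(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP genotype counts (n_ref_hom, n_het, n_alt_hom) over non-missing calls."""
    vals = g.dosage.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "n_ref_hom": np.sum(vals == 0.0, axis=0),
            "n_het": np.sum(vals == 1.0, axis=0),
            "n_alt_hom": np.sum(vals == 2.0, axis=0),
        },
        index=g.dosage.columns,
    )
    return out


@dataclass
class ExpressionMatrix:
    """feature x sample log2-scale expression values; NaN marks missing."""

    values: pd.DataFrame
    kind: str = MIRNA

    def __post_init__(self) -> None:
        if self.kind not in (MIRNA, MRNA):
            raise ValidationError(f"kind must be {MIRNA!r} or {MRNA!r}, got {self.kind!r}")
        _require_unique(self.values.index, "feature_id")
        _require_unique(self.values.columns, "sample_id")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)].copy(), self.kind)


def make_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample x covariate table: numeric, complete, unique samples."""
    _require_unique(df.index, "sample_id")
    df = df.astype(float)
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValidationError(f"covariate {col!r} contains missing values")
    return df


def make_catalog(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a catalog table and normalize optional columns.

    Required columns: ``snp_id``, ``annotation``. Optional: ``risk_allele``
    (single character or missing), ``evidence_level`` (1, 2 or 3, or missing),
    ``source`` (free text).
    """
    for col in ("snp_id", "annotation"):
        if col not in df.columns:
            raise ValidationError(f"catalog missing required column {col!r}")
    out = df.copy()
    for col in ("risk_allele", "source"):
        if col not in out.columns:
            out[col] = pd.NA
    if "evidence_level" not in out.columns:
        out["evidence_level"] = pd.NA
    out["evidence_level"] = out["evidence_level"].astype("Int64")
    levels = out["evidence_level"].dropna()
    if not levels.isin([1, 2, 3]).all():
        bad = levels[~levels.isin([1, 2, 3])].iloc[0]
        raise ValidationError(f"evidence_level {bad} not in {{1, 2, 3}}")
    if (out["snp_id"].astype(str).str.len() == 0).any():
        raise ValidationError("catalog contains empty snp_id")
    return out[CATALOG_COLUMNS]


def empty_association_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_id": pd.Series(dtype=str),
            "y_id": pd.Series(dtype=str),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "t": pd.Series(dtype=float),
            "p": pd.Series(dtype=float),
            "n": pd.Series(dtype=int),
            "q": pd.Series(dtype=float),
        }
    )
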