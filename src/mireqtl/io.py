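"""Readers and writers for the pipeline's on-disk formats.

Genotypes arrive as VCF (v4.x, biallelic, GT and optionally DS fields) or as a
sample x SNP dosage TSV accompanied by a SNP metadata TSV. Expression
matrices, covariates, catalogs and association tables are all TSV with a
header row; the only missing-value markers accepted are ``NA`` and the empty
cell.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ASSOC_COLUMNS,
    CATALOG_COLUMNS,
    SNP_COLUMNS,
    ExpressionMatrix,
    GenotypeMatrix,
    ParseError,
    ValidationError,
    compute_maf,
    make_catalog,
    make_covariates,
)

logger = logging.getLogger(__name__)

_NA_VALUES = ["NA", ""]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", keep_default_na=False,
                           na_values=_NA_VALUES, **kw)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_genotypes(path, format: str = "auto", dosage_mode: str = "round") -> GenotypeMatrix:
    """Read genotypes from VCF or from a dosage TSV.

    For VCF, GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    With ``dosage_mode="ds"`` the DS field (if present) is used instead and
    rounded to the nearest hard call in {0, 1, 2}. Multi-allelic records are
    skipped with a warning. For TSV, ``path`` is the sample x SNP dosage table
    (first column sample ids, header SNP ids); per-SNP metadata is read from a
    sibling ``<stem>.snps.tsv`` if present, otherwise minimal metadata is
    synthesized.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path, dosage_mode=dosage_mode)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, dosage_mode: str = "round") -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    meta_rows = []
    dosage_cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s at %s:%d",
                           var.ID, var.CHROM, var.POS)
            continue
        d = None
        if dosage_mode == "ds":
            ds = var.format("DS")
            if ds is not None:
                d = np.round(np.asarray(ds, dtype=float).ravel())
                d = np.clip(d, 0, 2)
        if d is None:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types, dtype=float)
            d = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(sid)
        meta_rows.append((sid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        dosage_cols.append(d)
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError("duplicate snp_id in VCF")
    dosage = pd.DataFrame(
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0)),
        index=samples, columns=snp_ids,
    )
    snps = pd.DataFrame(meta_rows, columns=SNP_COLUMNS[:5])
    snps["maf"] = np.nan
    snps["hwe_p"] = np.nan
    return compute_maf(GenotypeMatrix(dosage, snps))


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    _check_rectangular(path)
    df = _read_tsv(path, index_col=0)
    df.index.name = None
    try:
        dosage = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage cell ({exc})") from exc
    meta_path = Path(str(path)[: -len(".tsv")] + ".snps.tsv") if str(path).endswith(".tsv") else None
    if meta_path is not None and meta_path.exists():
        snps = read_snp_table(meta_path)
        snps = snps.loc[dosage.columns]
    else:
        snps = pd.DataFrame(
            {
                "chrom": "0",
                "pos": np.arange(1, dosage.shape[1] + 1),
                "ref_allele": "A",
                "alt_allele": "B",
                "maf": np.nan,
                "hwe_p": np.nan,
            },
            index=pd.Index(dosage.columns, name="snp_id"),
        )
    return compute_maf(GenotypeMatrix(dosage, snps))


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    """Write the dosage matrix and a ``<stem>.snps.tsv`` metadata sidecar."""
    path = Path(path)
    g.dosage.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
    write_snp_table(g.snps, Path(str(path)[: -len(".tsv")] + ".snps.tsv")
                    if str(path).endswith(".tsv") else path.with_suffix(".snps.tsv"))


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as a minimal VCF v4.2 file."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        vals = g.dosage.to_numpy(dtype=float)
        for j, sid in enumerate(g.snp_ids):
            row = g.snps.loc[sid]
            gts = "\t".join("./." if np.isnan(v) else gt_map[v] for v in vals[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{row['ref_allele']}\t"
                     f"{row['alt_allele']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_snp_table(path) -> pd.DataFrame:
    snps = _read_tsv(path)
    for col in SNP_COLUMNS[:5]:
        if col not in snps.columns:
            raise ValidationError(f"{path}: missing SNP metadata column {col!r}")
    for col in ("maf", "hwe_p"):
        if col not in snps.columns:
            snps[col] = np.nan
    return snps.set_index("snp_id")[SNP_COLUMNS[1:]]


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", na_rep="NA", index_label="snp_id")


def _check_rectangular(path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            n = len(line.rstrip("\n").split("\t"))
            if n != len(header):
                raise ParseError(
                    f"{path}:{lineno}: row has {n} fields, header has {len(header)}"
                )


def read_expression(path, kind: str) -> ExpressionMatrix:
    """Read a feature x sample expression TSV (first column feature ids)."""
    _check_rectangular(path)
    df = _read_tsv(path, index_col=0)
    df.index.name = None
    for col in df.columns:
        bad = df[col].map(lambda v: isinstance(v, str))
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric cell {df.loc[row, col]!r} at feature "
                f"{row!r}, sample {col!r}"
            )
    return ExpressionMatrix(df.astype(float), kind)


def write_expression(e: ExpressionMatrix, path) -> None:
    e.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id",
                    float_format="%.10g")


def read_covariates(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    df.index.name = None
    return make_covariates(df)


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_catalog(path) -> pd.DataFrame:
    return make_catalog(_read_tsv(path))


def write_catalog(cat: pd.DataFrame, path) -> None:
    cat[CATALOG_COLUMNS].to_csv(path, sep="\t", na_rep="NA", index=False)


def read_association_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ASSOC_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing association column {col!r}")
    return df[ASSOC_COLUMNS]


def write_association_table(records: pd.DataFrame, path) -> None:
    """Write an association table with fixed column order; %.17g preserves
    p-values through a write/read round trip."""
    out = records.copy()
    for col in ASSOC_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[ASSOC_COLUMNS].to_csv(path, sep="\t", na_rep="NA", index=False,
                              float_format="%.17g")
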