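"""End-to-end orchestration: preprocess -> scans -> enrichment -> annotation.

``run_pipeline`` sequences the stages on files named in a flat YAML config,
writes every intermediate table as TSV, and emits a machine-readable summary
(JSON) with the counts at each significance tier and all empirical p-values,
plus a log with the seed and per-stage timings. Any stage failure aborts
with the stage name; completed outputs are preserved.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotate import annotate_eqtls, pharmacogenetic_screen
from .association import (
    bonferroni_threshold,
    effect_size_summary,
    eqtl_scan,
    mirna_mrna_scan,
    significant_negative,
)
from .core import MIRNA, MRNA, ValidationError
from .enrichment import maf_matched_null_sets, overlap_enrichment, qq_curve
from .preprocess import (
    call_expressed,
    filter_snps,
    genotype_pcs,
    remove_hidden_factors,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown keys are rejected."""

    genotypes: str = ""
    genotype_format: str = "auto"
    mirna: str = ""
    mrna: str = ""
    covariates: str = ""
    catalog: str = ""
    out_dir: str = "mireqtl_out"
    min_expressed_frac: float = 0.75
    maf_min: float = 0.15
    hwe_alpha: float = 0.001
    n_pcs: int = 3
    n_factors: int = 4
    covariate_screen_alpha: float = 0.05
    fdr_alpha: float = 0.05
    bonferroni_alpha: float = 0.05
    suggestive_threshold: float = 1e-8
    eqtl_enrich_p: float = 1e-6
    catalog_p_max: float = 1e-4
    pharmacogenetic_p_max: float = 1e-3
    enrichment_B: int = 1000
    maf_bin_width: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.genotypes or not self.mirna:
            raise ValidationError("config must name genotypes and mirna inputs")
        for name, lo, hi in (("min_expressed_frac", 0, 1), ("maf_min", 0, 0.5),
                             ("hwe_alpha", 0, 1), ("fdr_alpha", 0, 1),
                             ("maf_bin_width", 0, 0.5)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValidationError(f"{name}={v} outside ({lo}, {hi}]")
        for path_attr in ("genotypes", "mirna", "mrna", "covariates", "catalog"):
            p = getattr(self, path_attr)
            if p and not Path(p).exists():
                raise ValidationError(f"{path_attr} path does not exist: {p}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    summary: dict = {"seed": cfg.seed, "stages": {}}
    timings: dict[str, float] = {}
    stage = "load_inputs"
    try:
        t0 = time.perf_counter()
        g = mio.read_genotypes(cfg.genotypes, format=cfg.genotype_format)
        mirna = mio.read_expression(cfg.mirna, MIRNA)
        mrna = mio.read_expression(cfg.mrna, MRNA) if cfg.mrna else None
        covariates = mio.read_covariates(cfg.covariates) if cfg.covariates else None
        catalog = mio.read_catalog(cfg.catalog) if cfg.catalog else None
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        mirna = call_expressed(mirna, cfg.min_expressed_frac)
        g = filter_snps(g, maf_min=cfg.maf_min, hwe_alpha=cfg.hwe_alpha)
        pcs = genotype_pcs(g, k=cfg.n_pcs) if cfg.n_pcs else None
        if covariates is not None and pcs is not None:
            covariates = covariates.join(pcs)
        elif pcs is not None:
            covariates = pcs
        mirna_resid, adj = remove_hidden_factors(mirna, k=cfg.n_factors)
        mio.write_expression(mirna_resid, out / "mirna_residual.tsv")
        mio.write_snp_table(g.snps, out / "snps_filtered.tsv")
        summary["stages"]["preprocess"] = {
            "n_expressed_mirnas": mirna.n_features,
            "n_snps_after_filter": g.n_snps,
            "n_factors_removed": adj.k,
            "median_pre_post_correlation": (
                None if adj.per_feature_correlation.empty
                else float(adj.per_feature_correlation.median())),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "pair_scan"
        pairs = None
        if mrna is not None:
            t0 = time.perf_counter()
            pairs = mirna_mrna_scan(mirna, mrna, fdr_alpha=cfg.fdr_alpha)
            mio.write_association_table(pairs, out / "mirna_mrna_associations.tsv")
            sig = significant_negative(pairs, cfg.fdr_alpha)
            ess = effect_size_summary(pairs, q_max=cfg.fdr_alpha)
            summary["stages"]["pair_scan"] = {
                "n_tests": len(pairs),
                "n_significant_negative": len(sig),
                "n_mirnas_with_negative_target": int(sig["x_id"].nunique()),
                "effect_size_mean": None if ess.n == 0 else ess.mean,
                "effect_size_sd": None if ess.n == 0 else ess.sd,
            }
            timings[stage] = time.perf_counter() - t0

        stage = "eqtl_scan"
        t0 = time.perf_counter()
        eqtls = eqtl_scan(mirna_resid, g, covariates=covariates,
                          covariate_screen_alpha=cfg.covariate_screen_alpha)
        mio.write_association_table(
            eqtls.drop(columns=["covariates_used"]), out / "eqtl_associations.tsv")
        bonf = bonferroni_threshold(cfg.bonferroni_alpha, g.n_snps, mirna.n_features)
        summary["stages"]["eqtl_scan"] = {
            "n_tests": len(eqtls),
            "bonferroni_threshold": bonf,
            "n_bonferroni_significant": int((eqtls["p"] < bonf).sum()),
            "n_suggestive": int((eqtls["p"] < cfg.suggestive_threshold).sum()),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "enrichment"
        if catalog is not None:
            t0 = time.perf_counter()
            query = [s for s in dict.fromkeys(catalog["snp_id"]) if s in g.snps.index]
            dropped = catalog["snp_id"].nunique() - len(query)
            if dropped:
                logger.warning("enrichment: %d catalog SNP(s) absent from the "
                               "filtered genotype pool dropped", dropped)
            enrich_summary = {}
            if query:
                nulls = maf_matched_null_sets(
                    query, g.snps, B=cfg.enrichment_B,
                    bin_width=cfg.maf_bin_width, seed=cfg.seed)
                target = set(eqtls.loc[eqtls["p"] < cfg.pharmacogenetic_p_max, "x_id"])
                res = overlap_enrichment(query, target, nulls)
                pd.DataFrame({"null_overlap": res.null_values}).to_csv(
                    out / "catalog_overlap_null.tsv", sep="\t", index=False)
                enrich_summary = {
                    "observed_overlap": res.observed,
                    "empirical_p": res.empirical_p,
                    "p_label": res.p_label,
                    "B": res.B,
                }
                catalog_p = eqtls.loc[eqtls["x_id"].isin(query), "p"]
                if len(catalog_p):
                    qq = qq_curve(catalog_p.to_numpy())
                    qq.to_csv(out / "catalog_qq.tsv", sep="\t", index=False)
            summary["stages"]["enrichment"] = enrich_summary
            timings[stage] = time.perf_counter() - t0

            stage = "annotate"
            t0 = time.perf_counter()
            annotated = annotate_eqtls(eqtls, catalog, g.snps, p_max=cfg.catalog_p_max)
            annotated.to_csv(out / "annotated_eqtls.tsv", sep="\t", index=False,
                             na_rep="NA", float_format="%.17g")
            summary["stages"]["annotate"] = {
                "n_annotated_records": len(annotated),
                "n_with_direction": int(annotated["direction_risk"].notna().sum()),
            }
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        raise
    summary["timings_sec"] = {k: round(v, 4) for k, v in timings.items()}
    _check_consistency(summary, out, cfg)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("pipeline complete; outputs in %s", out)
    return summary


def _check_consistency(summary: dict, out: Path, cfg: RunConfig) -> None:
    """Re-derive headline counts from the emitted TSVs; mismatch is a bug."""
    eqtl_path = out / "eqtl_associations.tsv"
    if eqtl_path.exists() and "eqtl_scan" in summary["stages"]:
        tab = mio.read_association_table(eqtl_path)
        st = summary["stages"]["eqtl_scan"]
        assert len(tab) == st["n_tests"], "eqtl count mismatch vs emitted TSV"
        assert int((tab["p"] < st["bonferroni_threshold"]).sum()) == \
            st["n_bonferroni_significant"], "bonferroni count mismatch"
    pair_path = out / "mirna_mrna_associations.tsv"
    if pair_path.exists() and "pair_scan" in summary["stages"]:
        tab = mio.read_association_table(pair_path)
        st = summary["stages"]["pair_scan"]
        n_sig = int(((tab["beta"] < 0) & (tab["q"] < cfg.fdr_alpha)).sum())
        assert n_sig == st["n_significant_negative"], "pair-scan count mismatch"
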